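import numpy as np
import pandas as pd
import pytest

from vacompare.bayes_engine import NO, UNKNOWN, YES, CaseIndicators


@pytest.fixture
def base3() -> pd.DataFrame:
    """Tiny 3-cause x 3-indicator probability base used in worked examples."""
    return pd.DataFrame(
        {
            "c1": [0.9, 0.2, 0.5],
            "c2": [0.1, 0.2, 0.5],
            "c3": [0.1, 0.2, 0.5],
        },
        index=["i1", "i2", "i3"],
    )


@pytest.fixture
def prior3() -> pd.Series:
    return pd.Series({"c1": 0.5, "c2": 0.3, "c3": 0.2})


def make_case(responses, case_id="c1", age_group=">=18y") -> CaseIndicators:
    """Build a case from a {indicator: Y/N/.} mapping."""
    return CaseIndicators(case_id=case_id, age_group=age_group, responses=responses)


def random_engine_instance(rng: np.random.Generator, max_causes=4, max_indicators=6):
    """Random small base + prior + fully-observed case, for oracle checks."""
    n_c = int(rng.integers(2, max_causes + 1))
    n_i = int(rng.integers(1, max_indicators + 1))
    causes = [f"c{k}" for k in range(n_c)]
    inds = [f"i{j}" for j in range(n_i)]
    base = pd.DataFrame(
        rng.uniform(0.02, 0.98, size=(n_i, n_c)), index=inds, columns=causes
    )
    prior = rng.dirichlet(np.ones(n_c))
    prior = pd.Series(prior / prior.sum(), index=causes)
    responses = {j: (YES if rng.random() < 0.5 else NO) for j in inds}
    if rng.random() < 0.3:  # some unknowns too
        responses[inds[0]] = UNKNOWN
    case = make_case(responses)
    return base, prior, case


def joint_posterior_oracle(base, prior, case, condition_on_no: bool):
    """Posterior by exhaustive enumeration of the full joint distribution.

    Builds P(cause, pattern) over all 2^n indicator patterns under
    conditional independence, then conditions on the observed evidence:
    the full Y/N pattern when ``condition_on_no``, else only the event
    {indicator = yes} for each yes indicator (unknown/no ignored).
    """
    import itertools

    inds = list(base.index)
    causes = list(base.columns)
    post = np.zeros(len(causes))
    yes = set(case.yes_indicators())
    no = set(case.no_indicators())
    for k, c in enumerate(causes):
        total = 0.0
        for pattern in itertools.product([0, 1], repeat=len(inds)):
            consistent = all(
                (inds[j] not in yes or pattern[j] == 1)
                and (not condition_on_no or inds[j] not in no or pattern[j] == 0)
                for j in range(len(inds))
            )
            if not consistent:
                continue
            p = float(prior[c])
            for j, ind in enumerate(inds):
                pj = float(base.loc[ind, c])
                p *= pj if pattern[j] == 1 else (1.0 - pj)
            total += p
        post[k] = total
    return pd.Series(post / post.sum(), index=causes)
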