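"""How physician coding accuracy drives panel-vs-model agreement.

Sweeps the coders' per-case accuracy theta and prints the kappa between
the three-physician panel's final causes and the engine's top causes:
noisier coders look less like the (deterministic) model.
"""

from vacompare import (
    GROUPS,
    SimulationConfig,
    cohen_kappa,
    cross_tabulate,
    harmonize_cohort,
    identity_map,
    interpret_cohort,
    simulate_cohort,
    simulate_physician_panel,
)

cfg = SimulationConfig(n_cases=1500, seed=11)
cases, truth, base = simulate_cohort(cfg)
model_groups = harmonize_cohort(
    interpret_cohort(cases, base, cfg.overall_csmf()), identity_map(GROUPS)
)

print("theta   kappa (95% CI)      panel indeterminate %")
for theta in (0.3, 0.5, 0.7, 0.9, 1.0):
    panel = simulate_physician_panel(
        truth, theta=theta, gamma=cfg.gamma, seed=cfg.seed, cause_labels=GROUPS
    )
    groups = harmonize_cohort(panel, identity_map(GROUPS))
    kap = cohen_kappa(cross_tabulate(groups, model_groups))
    indet = 100 * sum(a.indeterminate for a in panel) / len(panel)
    print(f"{theta:4.1f}   {kap.kappa:.3f} ({kap.ci_low:.3f}-{kap.ci_high:.3f})   {indet:5.1f}")

print(
    "\nReading: kappa rises monotonically with coder accuracy; the\n"
    "indeterminate share falls as unanimous three-way disagreement\n"
    "becomes rarer."
)
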