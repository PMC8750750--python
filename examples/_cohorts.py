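"""Shared cohort builder for the example scripts."""

import dynamet as dm


def linear_two_group_cohort(beta: float, seed: int) -> dm.MetabolomicsTensor:
    """10 normal + 10 A(7,6)-knock-down subjects from the linear open system."""
    config = dm.CohortConfig(
        groups=(
            dm.GroupSpec("normal", 10, dm.VariationSpec(beta=beta)),
            dm.GroupSpec("abnormal_A(7,6)", 10,
                         dm.VariationSpec(beta=beta, induced=(("A(7,6)", 0.5),))),
        ),
        time_grid=dm.linear_time_grid(),
        seed=seed,
    )
    return dm.generate_cohort(config, dm.default_linear_system())
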