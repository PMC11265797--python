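"""Named study-design presets for a transporter free-energy campaign.

These encode the sampling design of a full alternating-access free-energy
study of a proton-coupled peptide transporter: unbiased runs across
protonation/mutation conditions, 1D and 2D umbrella-sampling windows,
enhanced-sampling trials, constant-pH replicas, and alchemical binding
legs.  They serve as worked bookkeeping inputs and as default window
designs for the synthetic pipeline.
"""

from __future__ import annotations

from .campaign import CampaignBlock, CampaignPlan

__all__ = [
    "unbiased_occ_plan",
    "trials_plan",
    "pmf_1d_plan",
    "pmf_2d_plan",
    "cphmd_plan",
    "abfe_plan",
    "abfe_lambda_schedules",
    "N_2D_WINDOWS",
]

#: 24 umbrella centres x 2 force-constant tiers x 3 path replicates
N_2D_WINDOWS = 24 * 2 * 3


def unbiased_occ_plan() -> CampaignPlan:
    """Unbiased 1-us triplicates across 24 protonation/mutation conditions."""
    return CampaignPlan(
        "unbiased_occ",
        (
            CampaignBlock("occ_conditions", n_conditions=24, n_replicates=3,
                          n_windows=1, per_window_durations=(1000.0,)),
        ),
    )


def trials_plan() -> CampaignPlan:
    """Enhanced-sampling trial budget: metadynamics walkers, steered-MD
    path generation (pull + switch-off + relaxation), and the umbrella
    windows run from the steered paths in both directions."""
    return CampaignPlan(
        "enhanced_sampling_trials",
        (
            CampaignBlock("metadynamics_from_of", 1, 1, 8, (108.0,)),
            CampaignBlock("metadynamics_from_occ", 1, 1, 8, (213.0,)),
            CampaignBlock("smd_of_to_occ", 1, 1, 1, (200.0, 2.0, 48.0)),
            CampaignBlock("smd_occ_to_of", 1, 1, 1, (200.0, 2.0, 48.0)),
            CampaignBlock("reus_from_of_paths", 1, 1, 48, (92.0,)),
            CampaignBlock("reus_from_occ_paths", 1, 1, 48, (127.0,)),
        ),
    )


# Per-condition 1D umbrella sampling: 24 windows, three path replicates,
# per-replicate window durations in ns.
_PMF_1D_ROWS: tuple[tuple[str, tuple[float, ...]], ...] = (
    ("occ_of_standard", (266.0, 244.0, 244.0)),
    ("occ_of_h87_d342_prot", (327.0, 244.0, 244.0)),
    ("occ_if_standard", (242.0, 248.0, 246.0)),
    ("occ_if_e53_prot", (158.0, 155.0, 154.0)),
)


def pmf_1d_plan() -> CampaignPlan:
    return CampaignPlan(
        "pmf_1d",
        tuple(
            CampaignBlock(label, 1, 1, 24, durations)
            for label, durations in _PMF_1D_ROWS
        ),
    )


# Per-condition 2D umbrella sampling: 24 windows per replicate-tier
# combination, six combinations (3 replicates x 2 force-constant tiers).
_PMF_2D_ROWS: tuple[tuple[str, tuple[float, ...]], ...] = (
    ("occ_of_standard", (233, 195, 195, 208, 208, 207)),
    ("occ_of_h87_prot", (230, 200, 188, 201, 228, 229)),
    ("occ_of_d342_prot", (204, 232, 204, 224, 229, 207)),
    ("occ_of_h87_d342_prot", (196, 196, 195, 194, 194, 201)),
    ("occ_of_d342a", (182, 183, 206, 181, 183, 183)),
    ("occ_of_h87a", (176, 182, 183, 184, 182, 177)),
    ("occ_of_e53_prot", (185, 180, 209, 179, 218, 213)),
    ("occ_of_e56_prot", (194, 194, 194, 192, 193, 193)),
    ("occ_of_r206d_d342r", (227, 213, 183, 222, 211, 180)),
    ("occ_of_holo_standard", (200, 196, 195, 200, 194, 201)),
    ("occ_of_holo_e53_prot", (185, 180, 210, 179, 218, 213)),
    ("occ_of_holo_e56_prot", (194, 194, 194, 192, 193, 193)),
    ("occ_of_holo_h87_d342_prot", (198, 191, 198, 190, 182, 201)),
    ("occ_if_standard", (197, 216, 203, 192, 197, 199)),
    ("occ_if_e53_prot", (197, 208, 199, 192, 193, 195)),
    ("occ_if_e622_prot", (199, 201, 200, 196, 217, 197)),
    ("occ_if_e53_e622_prot", (193, 237, 240, 187, 250, 200)),
    ("occ_if_holo_standard", (190, 195, 191, 196, 192, 197)),
    ("occ_if_holo_e53_prot", (189, 196, 197, 199, 189, 198)),
    ("occ_if_holo_e622_prot", (194, 191, 206, 197, 198, 199)),
    ("occ_if_holo_e53_e622_prot", (197, 198, 180, 195, 190, 204)),
)


def pmf_2d_plan() -> CampaignPlan:
    return CampaignPlan(
        "pmf_2d",
        tuple(
            CampaignBlock(label, 1, 1, 24, tuple(float(d) for d in durations))
            for label, durations in _PMF_2D_ROWS
        ),
    )


def cphmd_plan() -> CampaignPlan:
    """Constant-pH triplicates: 4 conditions x 3 replicates x 8 pH windows
    of 1 us each (pH 0-7)."""
    return CampaignPlan(
        "cphmd",
        (
            CampaignBlock("of_occ_apo_holo", n_conditions=4, n_replicates=3,
                          n_windows=8, per_window_durations=(1000.0,)),
        ),
    )


def abfe_plan() -> CampaignPlan:
    """Alchemical binding legs: 4 conditions x 7 boxes x 44 lambda windows
    at 31.2 ns per window (1.2 ns equilibration + 30 ns production)."""
    return CampaignPlan(
        "abfe",
        (
            CampaignBlock("double_decoupling", n_conditions=4, n_replicates=7,
                          n_windows=44, per_window_durations=(31.2,)),
        ),
    )


def abfe_lambda_schedules() -> dict[str, tuple[float, ...]]:
    """The alchemical lambda schedules of the binding-leg design: Boresch
    restraint switch-on, then charge annihilation at even 0.1 spacing, then
    van-der-Waals annihilation at even 0.05 spacing."""
    restraint = (0.0, 0.01, 0.025, 0.05, 0.075, 0.1,
                 0.2, 0.3, 0.4, 0.5, 0.6, 0.8, 1.0)
    coulomb = tuple(round(0.1 * i, 10) for i in range(11))
    vdw = tuple(round(0.05 * i, 10) for i in range(21))
    return {"restraint": restraint, "coulomb": coulomb, "vdw": vdw}
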