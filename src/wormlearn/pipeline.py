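"""End-to-end synthetic-scenario pipeline: conditioning experiment in silico.

Each stage generates a synthetic dataset that mimics one assay of the
conditioning study — chemotaxis plates, EGL-4 cell images, AWC calcium
recordings, optogenetic reversal trials — runs the corresponding analysis,
and writes tidy CSV outputs plus a JSON run manifest.  The stage functions
are the single source of the study conditions (cohort sizes, effect sizes,
noise) used by the analysis drivers, the CLI and the acceptance checks.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import calcium, chemotaxis, nuclear, reversals, synth
from .io import config_hash, load_config, logger, write_manifest

__all__ = [
    "chemotaxis_stage",
    "nuclear_stage",
    "calcium_stage",
    "reversal_stage",
    "run_pipeline",
    "NUCLEAR_COHORT",
    "CALCIUM_COHORT",
    "REVERSAL_COHORT",
]

# Study conditions for the synthetic scenarios (cohort sizes follow the
# assay designs: 79-90 cells per condition for the nuclear assay, ~25
# animals per calcium cohort arm (24 used here), 7 trials of ~20 animals
# for optogenetics, 10 plates per chemotaxis cell).
NUCLEAR_COHORT = {
    "n_per_condition": 80,
    "naive_index": 1.0,
    "conditioned_index": 1.5,
    "between_animal_sd": 0.1,
    "pixel_noise_sd": 5.0,
    "awc_on_fraction": 0.5,  # only the AWC-ON-like half shifts
    "image_size": 48,
}
CALCIUM_COHORT = {"n_per_arm": 24, "fs": 10.0, "post_s": 360.0}
REVERSAL_COHORT = {
    "n_trials": 7,
    "n_animals": 20,
    "duration_s": 1200.0,
    "fs": 4.0,
    "conditioned_r_stim": 2.0,  # conditioning abolishes the light-evoked increase
}
CHEMOTAXIS_COHORT = {
    "plates_per_cell": 10,
    "animals_per_plate": 120,
    # end-point zone probabilities (odor, control, other, origin)
    "naive_probs": (0.80, 0.05, 0.10, 0.05),
    "conditioned_probs": (0.30, 0.35, 0.30, 0.05),
}


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------

def chemotaxis_stage(seed: int = 0, learning_defective_group: str = "mutant") -> dict:
    """Aversive-learning chemotaxis experiment: 2x2 condition x genotype design.

    Wild-type animals lose butanone attraction after conditioning; the
    learning-defective group stays attracted, so the learning effect appears
    as a condition-by-genotype interaction on plate-level indices.
    """
    cc = CHEMOTAXIS_COHORT
    plates = []
    seeds = iter(_spawn_seeds(seed, 4 * cc["plates_per_cell"]))
    for group in ("WT", learning_defective_group):
        for condition in ("naive", "conditioned"):
            learned = group == "WT" and condition == "conditioned"
            probs = cc["conditioned_probs"] if learned else cc["naive_probs"]
            for k in range(cc["plates_per_cell"]):
                plates.append(
                    synth.simulate_plate(
                        *probs,
                        n_animals=cc["animals_per_plate"],
                        seed=next(seeds),
                        condition=condition,
                        group=group,
                        plate_id=f"{group}-{condition}-{k}",
                    )
                )
    table, excluded = chemotaxis.score_plates(plates)
    result, cells = chemotaxis.learning_interaction(table, "condition", "group")
    return {
        "plates": plates,
        "assay_table": table,
        "excluded": excluded,
        "interaction": result,
        "cell_means": cells,
        "learning_index_wt": chemotaxis.learning_index(table, "WT"),
        "learning_index_mutant": chemotaxis.learning_index(table, learning_defective_group),
    }


def nuclear_stage(seed: int = 0) -> dict:
    """EGL-4 nuclear-translocation assay on synthetic cell images.

    The imaged cells are an unmarked 50:50 mixture of AWC-ON- and
    AWC-OFF-like neurons; conditioning shifts the nuclear index only in the
    AWC-ON-like half, and the KS comparison must detect the mixture shift.
    """
    nc = NUCLEAR_COHORT
    rng = np.random.default_rng(seed)
    indices = {"naive": [], "conditioned": []}
    img_seed = iter(_spawn_seeds(seed, 2 * nc["n_per_condition"]))
    for condition in ("naive", "conditioned"):
        for i in range(nc["n_per_condition"]):
            shifted = condition == "conditioned" and rng.random() < nc["awc_on_fraction"]
            target = nc["conditioned_index"] if shifted else nc["naive_index"]
            target = max(0.2, target + rng.normal(0, nc["between_animal_sd"]))
            img = synth.simulate_cell_image(
                target,
                size=nc["image_size"],
                noise_sd=nc["pixel_noise_sd"],
                seed=next(img_seed),
            )
            indices[condition].append(nuclear.nuclear_index_of_image(img))
    D, p = nuclear.ks_two_sample(indices["naive"], indices["conditioned"])
    records = pd.DataFrame(
        [
            {"condition": c, "animal_id": f"{c}{i:03d}", "nuclear_index": v}
            for c in indices
            for i, v in enumerate(indices[c])
        ]
    )
    return {"records": records, "D": D, "p": p, "indices": indices}


def calcium_stage(
    seed: int = 0, n_per_arm: int | None = None, params: synth.AwcModelParams | None = None
) -> dict:
    """Dose-response calcium imaging of naive vs conditioned cohorts."""
    cc = CALCIUM_COHORT
    n = n_per_arm or cc["n_per_arm"]
    protocol = synth.make_odor_protocol()
    s_naive, s_cond = _spawn_seeds(seed, 2)
    if params is None:
        params = synth.AwcModelParams()
    naive_params = synth.AwcModelParams(**{**params.__dict__, "seed": s_naive})
    cond_params = synth.AwcModelParams(**{**params.__dict__, "seed": s_cond})
    naive = synth.simulate_awc_cohort(naive_params, protocol, False, n, cc["fs"], cc["post_s"])
    cond = synth.simulate_awc_cohort(cond_params, protocol, True, n, cc["fs"], cc["post_s"])
    naive_summary, naive_animals = calcium.dose_response_table(naive, protocol)
    cond_summary, cond_animals = calcium.dose_response_table(cond, protocol)
    welch = calcium.per_concentration_welch(naive_animals, cond_animals)
    shift = calcium.dynamic_range_shift(naive_summary, cond_summary)
    return {
        "protocol": protocol,
        "naive_summary": naive_summary,
        "conditioned_summary": cond_summary,
        "naive_animals": naive_animals,
        "conditioned_animals": cond_animals,
        "welch": welch,
        "shift": shift,
    }


def reversal_stage(seed: int = 0, use_detector: bool = True) -> dict:
    """Optogenetic reversal experiment: naive vs conditioned trial groups.

    Naive animals show a light-evoked jump in reversal initiation
    (r_stim > r_base); in conditioned animals the coupling is abolished
    (r_stim = r_base).  Each trial is analyzed over pulses 6-10 and the
    trial groups compared with a Welch t-test.
    """
    rc = REVERSAL_COHORT
    schedule = synth.make_light_schedule()
    trial_seeds = _spawn_seeds(seed, 2 * rc["n_trials"])
    groups: dict[str, list[reversals.TrialSummary]] = {"naive": [], "conditioned": []}
    timecourses = {}
    all_tracks = {}
    for gi, gname in enumerate(("naive", "conditioned")):
        r_stim = 10.0 if gname == "naive" else rc["conditioned_r_stim"]
        group_tracks = []
        for k in range(rc["n_trials"]):
            params = synth.ReversalModelParams(
                r_stim=r_stim, seed=trial_seeds[gi * rc["n_trials"] + k]
            )
            tracks = synth.simulate_tracks(
                params, schedule, rc["n_animals"], rc["duration_s"], rc["fs"],
                trial_id=f"{gname}-{k}",
            )
            if use_detector:
                events = [reversals.detect_reversals(tr) for tr in tracks]
            else:
                events = [tr.events for tr in tracks]
            groups[gname].append(
                reversals.analyze_pulses(events, schedule, trial_id=f"{gname}-{k}")
            )
            group_tracks.extend(tracks)
        timecourses[gname] = reversals.reversal_fraction_timecourse(
            group_tracks, schedule, analyzed=[6, 7, 8, 9, 10]
        )
        all_tracks[gname] = group_tracks
    test = reversals.compare_groups(groups["naive"], groups["conditioned"])
    return {
        "schedule": schedule,
        "groups": groups,
        "test": test,
        "timecourses": timecourses,
        "tracks": all_tracks,
    }


# ---------------------------------------------------------------------------

def run_pipeline(
    config_path: str | None = None,
    outdir: str | Path = "results",
    seed: int | None = None,
    figures: bool = True,
) -> dict:
    """Run the full synthetic conditioning experiment and write all outputs."""
    cfg = load_config(config_path)
    if seed is None:
        seed = int(cfg["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_seeds = _spawn_seeds(seed, 4)
    outputs = []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df = df.copy()
        df["config_hash"] = config_hash(cfg)
        df["seed"] = seed
        df.to_csv(path, index=False)
        outputs.append(str(path))

    logger.info("chemotaxis stage (seed %d)", stage_seeds[0])
    chem = chemotaxis_stage(stage_seeds[0])
    _write(chem["assay_table"], "chemotaxis_indices.csv")
    _write(chem["cell_means"], "chemotaxis_cell_means.csv")
    _write(
        pd.DataFrame(
            [{
                "F_interaction": chem["interaction"].statistic,
                "p": chem["interaction"].p,
                "learning_index_wt": chem["learning_index_wt"],
                "learning_index_mutant": chem["learning_index_mutant"],
            }]
        ),
        "chemotaxis_anova.csv",
    )

    logger.info("nuclear-localization stage (seed %d)", stage_seeds[1])
    nuc = nuclear_stage(stage_seeds[1])
    _write(nuc["records"], "nuclear_indices.csv")
    _write(pd.DataFrame([{"ks_D": nuc["D"], "ks_p": nuc["p"]}]), "nuclear_ks.csv")

    logger.info("calcium dose-response stage (seed %d)", stage_seeds[2])
    cal = calcium_stage(stage_seeds[2])
    _write(cal["naive_summary"].assign(cohort="naive"), "calcium_naive_summary.csv")
    _write(cal["conditioned_summary"].assign(cohort="conditioned"), "calcium_conditioned_summary.csv")
    _write(cal["welch"], "calcium_welch.csv")
    _write(pd.DataFrame([cal["shift"].as_dict()]), "calcium_shift.csv")

    logger.info("reversal-optogenetics stage (seed %d)", stage_seeds[3])
    rev = reversal_stage(stage_seeds[3])
    _write(
        pd.DataFrame(
            [
                {"trial_id": s.trial_id, "group": g, "during_minus_after": s.during_minus_after,
                 "n_animals": s.n_animals}
                for g in ("naive", "conditioned")
                for s in rev["groups"][g]
            ]
        ),
        "reversal_trials.csv",
    )
    _write(
        pd.DataFrame(
            [{"t": rev["test"].statistic, "df": rev["test"].df, "p": rev["test"].p}]
        ),
        "reversal_test.csv",
    )

    if figures:
        _make_figures(outdir, nuc, cal, rev, outputs)
    write_manifest(outdir / "run_manifest.json", cfg, seed, outputs)
    return {"chemotaxis": chem, "nuclear": nuc, "calcium": cal, "reversals": rev,
            "outputs": outputs}


def _make_figures(outdir: Path, nuc, cal, rev, outputs: list) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
    for name, tbl, color in (
        ("naive", cal["naive_summary"], "k"),
        ("conditioned", cal["conditioned_summary"], "r"),
    ):
        axes[0].errorbar(
            tbl["concentration"], tbl["mean_magnitude"], yerr=tbl["sem_magnitude"],
            label=name, color=color, marker="o",
        )
        ok = tbl["n_half_time"] > 0
        axes[1].errorbar(
            tbl.loc[ok, "concentration"], tbl.loc[ok, "mean_half_time"],
            yerr=tbl.loc[ok, "sem_half_time"], label=name, color=color, marker="o",
        )
    for ax, ylab in zip(axes, ["response magnitude (norm. dF)", "recovery half-time (s)"]):
        ax.set_xscale("log")
        ax.set_xlabel("butanone (M)")
        ax.set_ylabel(ylab)
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(figdir / "dose_response.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 3.2))
    for cond, color in (("naive", "k"), ("conditioned", "r")):
        e = np.sort(nuc["indices"][cond])
        ax.step(e, np.arange(1, len(e) + 1) / len(e), color=color, label=cond)
    ax.set_xlabel("AWC nuclear index")
    ax.set_ylabel("cumulative fraction")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(figdir / "nuclear_ecdf.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.2))
    for cond, color in (("naive", "k"), ("conditioned", "r")):
        tc = rev["timecourses"][cond]
        ax.plot(tc["t_rel"], tc["fraction_reversing"], color=color, label=cond)
    ax.axvspan(0, 20, color="lightblue", alpha=0.5)
    ax.set_xlabel("time from light onset (s)")
    ax.set_ylabel("fraction reversing")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(figdir / "reversal_timecourse.png", dpi=120)
    plt.close(fig)
    outputs.extend(
        str(figdir / n)
        for n in ("dose_response.png", "nuclear_ecdf.png", "reversal_timecourse.png")
    )
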