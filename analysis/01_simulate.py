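#!/usr/bin/env python
"""Generate example synthetic datasets in the raw file formats the pipeline reads.

Writes small specimens of each input type under results/data/: plate-count
tables, a calcium-trace table with its stimulus protocol, cell-plane images
with ROI sidecars, and centroid tracks with the light schedule.  The later
drivers regenerate their full cohorts in memory; these files document the
on-disk interchange formats.
"""

from pathlib import Path

from wormlearn import io, synth

SEED = 20260101
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    plates = [
        synth.simulate_plate(0.8, 0.05, 0.1, 0.05, 120, seed=SEED + k,
                             condition="naive", group="WT", plate_id=f"naive-{k}")
        for k in range(3)
    ] + [
        synth.simulate_plate(0.3, 0.35, 0.3, 0.05, 120, seed=SEED + 10 + k,
                             condition="conditioned", group="WT", plate_id=f"cond-{k}")
        for k in range(3)
    ]
    io.write_plate_counts(OUT / "plate_counts.csv", plates)

    # short two-concentration protocol at 2 Hz keeps the specimen file small;
    # the full six-concentration cohorts are regenerated in memory downstream
    protocol = synth.make_odor_protocol([1.1e-7, 1.1e-6])
    io.write_protocol(OUT / "odor_protocol.yaml", protocol)
    params = synth.AwcModelParams(seed=SEED)
    traces = synth.simulate_awc_cohort(
        params, protocol, conditioned=False, n_animals=1, fs=2.0, post_s=120.0
    )
    io.write_traces(OUT / "awc_traces_naive.csv", traces)

    for k, target in enumerate((1.0, 1.5)):
        img = synth.simulate_cell_image(target, size=48, noise_sd=5.0, seed=SEED + k)
        io.write_cell_image(OUT / f"cell_{k}.csv", img)

    schedule = synth.make_light_schedule()
    io.write_protocol(OUT / "light_schedule.yaml", schedule)
    tracks = synth.simulate_tracks(
        synth.ReversalModelParams(seed=SEED), schedule, n_animals=1, duration_s=200.0
    )
    io.write_tracks(OUT / "worm_tracks.csv", tracks)

    print(f"wrote example datasets to {OUT}")
    print(f"  {len(plates)} plates, {len(traces)} calcium traces, 2 cell images, {len(tracks)} tracks")


if __name__ == "__main__":
    main()
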