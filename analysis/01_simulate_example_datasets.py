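"""Generate one example dataset per modality, with ground truth, under
results/data/: an MEA well spike table, a calcium session (traces + position
track), and a puncta image (TIFF + mask + soma sidecar).

These are the same generators the tests and acceptance checks use; this
script exists so the on-disk formats can be inspected and fed back through
the CLI.
"""

import argparse
from pathlib import Path

from neuroquant import io as nio
from neuroquant import synth

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    out = ROOT / "results" / "data"
    out.mkdir(parents=True, exist_ok=True)

    well_cfg = synth.WellSimConfig(
        duration=300.0, background_rate=1.0,
        burst_spec=[(e, 10.0 + 7.0 * e, 6, 0.02) for e in range(8)],
        network_burst_spec=[(200.0, 8, 10, 0.004)], seed=seed)
    well, truth = synth.gen_spike_well(well_cfg)
    nio.write_spike_csv(out / "well_spikes.csv", [well])
    nio.write_json(out / "well_ground_truth.json", {
        "bursts": [(e, list(t)) for e, t in truth.bursts],
        "network_bursts": [(m, list(t)) for m, t in truth.network_bursts]})
    print(f"well: {sum(len(t) for t in well.trains)} spikes, "
          f"{len(truth.bursts)} injected bursts, "
          f"{len(truth.network_bursts)} network bursts "
          f"-> {out / 'well_spikes.csv'}")

    plan = [("movement", 30.0, 15.0), ("stationary", 30.0, 2.0)] * 5
    cal_cfg = synth.CalciumSimConfig(
        n_cells=20, duration=300.0,
        event_rate={"movement": 0.121, "stationary": 0.075},
        epoch_plan=plan, seed=seed + 1)
    traces, track, cal_truth = synth.gen_calcium_session(cal_cfg)
    nio.write_traces_csv(out / "calcium_traces.csv", traces)
    nio.write_track_csv(out / "position_track.csv", track)
    nio.write_json(out / "calcium_ground_truth.json", {
        "event_times": [list(t) for t in cal_truth.event_times],
        "epochs": cal_truth.epochs})
    n_events = sum(len(t) for t in cal_truth.event_times)
    print(f"calcium: {cal_cfg.n_cells} cells x {cal_cfg.duration:.0f} s, "
          f"{n_events} true events -> {out / 'calcium_traces.csv'}")

    img_cfg = synth.random_puncta_config(
        0.3, (0.3, 0.8), peak=60.0, seed=seed + 2,
        base=synth.default_neuron_image_config(noise_sd=3.0))
    img, mask, img_truth = synth.gen_puncta_image(img_cfg)
    nio.write_image_tiff(out / "puncta_image.tif", img)
    nio.write_mask_tiff(out / "cell_mask.tif", mask)
    nio.write_soma_json(out / "soma.json", img_cfg.soma_center,
                        img_cfg.pixel_size)
    img_truth.to_csv(out / "puncta_ground_truth.csv", index=False)
    print(f"image: {len(img_truth)} puncta on a "
          f"{img.shape[0]}x{img.shape[1]} field -> {out / 'puncta_image.tif'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
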