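"""Score punctate vs diffuse dendritic localization with the distribution
index (mean absolute deviation of the mean-normalized 15-um line profile).

Clustered profiles emulate scaffold-bound protein (discrete puncta along the
dendrite); diffuse profiles emulate a construct that has lost its synaptic
targeting. The index separates the two groups cleanly — the direction that
distinguishes full-length from truncated constructs in the source assay.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from neuroquant import stats, synth
from neuroquant.profiles import distribution_index

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int, n_per_group: int) -> None:
    rng = np.random.default_rng(seed)
    rows = []
    for mode in ("clustered", "diffuse"):
        for _ in range(n_per_group):
            prof = synth.gen_intensity_profile(mode, noise_sd=2.0,
                                               seed=int(rng.integers(2**31)))
            rows.append({"mode": mode, "di": distribution_index(prof),
                         "mean_intensity": float(prof.intensities.mean())})
    df = pd.DataFrame(rows)
    cl = df.loc[df["mode"] == "clustered", "di"]
    di = df.loc[df["mode"] == "diffuse", "di"]
    cmp = stats.compare_groups(di, cl)
    print(f"distribution index: diffuse {cmp.mean_a:.3f} +/- {cmp.sem_a:.3f}, "
          f"clustered {cmp.mean_b:.3f} +/- {cmp.sem_b:.3f} "
          f"(n = {n_per_group}/group)")
    print(f"two-tailed Student's t: t = {cmp.statistic:.1f}, p = {cmp.p:.2g}; "
          f"clustered/diffuse ratio {cmp.mean_b / cmp.mean_a:.1f}x")

    out = ROOT / "results" / "distribution_index.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-per-group", type=int, default=18)
    a = ap.parse_args()
    main(a.seed, a.n_per_group)
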