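"""Angular statistics of MT anchoring sites around cell centroids.

Samples anchoring-site angles from a bimodal distribution at the
proximal-distal boundaries (0 and 180 degrees), bins them the standard
way (20 bins of 18 degrees), and tests the P-vs-D half-plane split with
the exact binomial test.  A uniform control sample shows what no
polarization looks like.

Writes results/anchoring_stats.csv and results/anchoring_histogram.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from wingpol.anchoring import AnchoringSet, anchoring_histogram, axial_bias_stats
from wingpol.synth import make_anchoring_angles

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 925


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows, hist_rows = [], []
    for label, kappa in (("bimodal_PD", 6.0), ("uniform", 0.0)):
        angles = make_anchoring_angles(n=200, modes_deg=[0.0, 180.0],
                                       kappa=kappa, seed=SEED)
        sites = AnchoringSet(angles)
        stats = axial_bias_stats(sites)
        hist = anchoring_histogram(sites, n_bins=20)
        rows.append({"sample": label, **stats})
        for k, count in enumerate(hist):
            hist_rows.append({"sample": label, "bin_start_deg": k * 18.0,
                              "count": int(count)})
        print(f"{label:10s}: axial R = {stats['axial_resultant']:.3f}, "
              f"raw R = {stats['raw_resultant']:.3f}, "
              f"P-vs-D binomial p = {stats['distal_vs_proximal_p']:.2g}")
    pd.DataFrame(rows).to_csv(OUT / "anchoring_stats.csv", index=False)
    pd.DataFrame(hist_rows).to_csv(OUT / "anchoring_histogram.csv", index=False)
    print("bimodal anchoring shows high axial order with raw resultant near 0 "
          "(sites on both P-D boundaries)")
    print(f"wrote {OUT / 'anchoring_stats.csv'}")


if __name__ == "__main__":
    sys.exit(main())
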