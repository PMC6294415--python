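"""Demonstrate the centroid's edge bias and the Gaussian-bank correction.

For noiseless Gaussian tuning curves with modes across the stimulus
range and widths from 1 to 12 ERB_N, tabulates the raw centroid error
(strongly biased towards mid-range near the edges) against the
bank-matched (debiased) mode error.  Writes results/debias_bias.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tonocore.scale import hz_to_cam
from tonocore.tuning import STIM_CAM, GaussianBank, centroid, debias

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    bank = GaussianBank()
    rows = []
    for m_hz in np.linspace(251, 6009, 25):
        m = hz_to_cam(m_hz)
        for s in (1.0, 2.0, 4.0, 8.0, 12.0):
            beta = np.exp(-((STIM_CAM - m) ** 2) / (2 * s * s))
            rows.append({
                "mode_hz": round(float(m_hz)),
                "mode_cam": m,
                "width_erb": s,
                "centroid_error_cam": abs(centroid(beta) - m),
                "debiased_error_cam": abs(debias(beta, bank) - m),
            })
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "debias_bias.csv", index=False)
    edges = df[df.mode_hz.isin([251, 6009])]
    mid = df[(df.mode_hz > 1000) & (df.mode_hz < 3000)]
    print("centroid error at range edges: "
          f"median {edges.centroid_error_cam.median():.2f} Cam "
          f"(max {edges.centroid_error_cam.max():.2f})")
    print("debiased error at range edges: "
          f"median {edges.debiased_error_cam.median():.2f} Cam")
    print("debiased error mid-range:      "
          f"median {mid.debiased_error_cam.median():.3f} Cam")
    print("note: for 1-ERB-wide curves near the edges the (C, S) pair is "
          "scale-invariant and nearly flat along a (mode, width) family, "
          "so individual matches can land far from the true mode")
    print(f"wrote {OUT / 'debias_bias.csv'}")


if __name__ == "__main__":
    main()
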