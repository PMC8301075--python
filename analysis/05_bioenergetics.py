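#!/usr/bin/env python
"""Mitochondrial assay computations on synthetic example measurements.

Builds small synthetic Fura-2 ratio records and Seahorse-style OCR traces
for a euploid control group and a lower-respiring trisomic group, then runs
the closed-form computations: Grynkiewicz calcium calibration, FCCP
peak-over-basal percentages, Mito Stress respiratory indices, and
percent-of-control normalization.  Tables land in results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from t21meta.bioenergetics import (
    CalciumCalibration,
    OCRTrace,
    fccp_peak_percent,
    grynkiewicz_ca,
    ocr_indices,
    percent_of_control,
)

ROOT = Path(__file__).resolve().parents[1]


def synthetic_ocr_traces(rng) -> dict[str, tuple[str, OCRTrace]]:
    """Three wells per group; trisomic wells respire ~35% lower (synthetic)."""
    traces = {}
    for group, scale in (("euploid", 1.0), ("trisomic", 0.65)):
        for i in range(3):
            levels = np.array([100.0, 40.0, 130.0, 10.0]) * scale
            ocr = np.concatenate([[lvl] * 3 for lvl in levels])
            ocr = ocr + rng.normal(0, 1.0, ocr.size)
            trace = OCRTrace(np.arange(12.0), ocr, 3, 6, 9)
            traces[f"{group}_{i + 1}"] = (group, trace)
    return traces


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    rng = np.random.default_rng(args.seed)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    # --- calcium: basal and post-FCCP ratios per cell (synthetic) ----------
    calib = CalciumCalibration(rmin=0.5, rmax=2.5, beta=1.0)
    n_cells = 40
    rows = []
    for group, basal_r, peak_gain in (("euploid", 0.85, 0.25), ("trisomic", 0.95, 0.45)):
        for c in range(n_cells):
            r_basal = basal_r + rng.normal(0, 0.03)
            r_peak = r_basal + peak_gain + rng.normal(0, 0.05)
            ca_b = grynkiewicz_ca(r_basal, calib)
            ca_p = grynkiewicz_ca(r_peak, calib)
            rows.append(
                {
                    "group": group,
                    "cell": f"{group}_{c + 1}",
                    "basal_ca_nm": round(ca_b, 1),
                    "peak_ca_nm": round(ca_p, 1),
                    "fccp_peak_pct": round(fccp_peak_percent(ca_b, ca_p), 1),
                }
            )
    calcium = pd.DataFrame(rows)
    calcium.to_csv(results / "calcium_fccp_response.tsv", sep="\t", index=False)

    # --- OCR indices and percent-of-control ---------------------------------
    traces = synthetic_ocr_traces(rng)
    idx_rows = []
    for well, (group, trace) in traces.items():
        idx_rows.append({"well": well, "group": group, **ocr_indices(trace).as_dict()})
    indices = pd.DataFrame(idx_rows)

    ctrl = indices[indices["group"] == "euploid"]
    norm = indices.copy()
    for col in ("basal", "atp_linked", "maximal", "spare"):
        norm[col] = percent_of_control(indices[col], ctrl[col]).round(1)
    indices.to_csv(results / "ocr_indices.tsv", sep="\t", index=False,
                   float_format="%.2f")
    norm.to_csv(results / "ocr_indices_pct_of_control.tsv", sep="\t", index=False)

    grp_ca = calcium.groupby("group")["fccp_peak_pct"].mean().round(1)
    grp_ocr = norm.groupby("group")[["basal", "atp_linked", "maximal"]].mean().round(1)
    print("mean FCCP-induced calcium rise over basal (%):")
    print(grp_ca.to_string())
    print("\nrespiratory indices as percent of euploid control mean:")
    print(grp_ocr.to_string())
    print(
        "\n(euploid rows sit at ~100 by construction; trisomic wells were "
        "synthesized ~35% lower, and a larger FCCP calcium release marks "
        "higher mitochondrial calcium load)"
    )


if __name__ == "__main__":
    main()
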