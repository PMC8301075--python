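"""Closed-form mitochondrial assay computations.

Two wet-lab readouts are covered:

Fura-2 ratiometric calcium imaging
    The Grynkiewicz calibration converts a background-corrected fluorescence
    ratio R (340/380 nm excitation) into a cytosolic free-calcium
    concentration::

        [Ca2+] = Kd * beta * (R - Rmin) / (Rmax - R)      [nM]

    with Kd = 224 nM for Fura-2, Rmin/Rmax the ratios at zero and saturating
    calcium, and beta = Sf2/Sb2 the 380-nm fluorescence ratio of free to
    bound dye.  Mitochondrial calcium efflux triggered by the uncoupler FCCP
    is summarized as the percentage rise of the post-FCCP peak over baseline.

Seahorse Mito Stress oxygen-consumption traces
    OCR is measured at baseline and after sequential injection of oligomycin
    (ATP-synthase inhibitor), FCCP (uncoupler) and antimycin-A/rotenone
    (ETC block).  Standard indices::

        non_mito   = mean OCR after antimycin/rotenone
        basal      = last pre-oligomycin OCR - non_mito
        atp_linked = last pre-oligomycin OCR - min post-oligomycin OCR
        maximal    = max post-FCCP OCR - non_mito
        spare      = maximal - basal

    The ``reading="mean"`` variant uses segment means instead of
    last/min/max extrema.  Group summaries are reported as percent of the
    control-group mean (control mean == 100 by construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import CalibrationError, DataError, TraceError

logger = logging.getLogger(__name__)

__all__ = [
    "CalciumCalibration",
    "grynkiewicz_ca",
    "fccp_peak_percent",
    "OCRTrace",
    "RespirationIndices",
    "ocr_indices",
    "percent_of_control",
    "read_ocr_table",
    "ocr_indices_table",
    "read_calcium_table",
    "calcium_table",
]

FURA2_KD_NM = 224.0

PHASES = ("baseline", "oligomycin", "fccp", "antimycin_rotenone")


@dataclass
class CalciumCalibration:
    """Fura-2 calibration constants: Kd (nM), ratio bounds, beta = Sf2/Sb2."""

    rmin: float
    rmax: float
    beta: float | None = None
    kd: float = FURA2_KD_NM

    def __post_init__(self) -> None:
        if not (self.rmax > self.rmin > 0):
            raise DataError(f"calibration: need Rmax > Rmin > 0, got {self.rmin}, {self.rmax}")
        if self.kd <= 0:
            raise DataError("calibration: Kd must be > 0")
        if self.beta is None:
            logger.warning("calibration: beta (Sf2/Sb2) not supplied; defaulting to 1.0")
            self.beta = 1.0
        if self.beta <= 0:
            raise DataError("calibration: beta must be > 0")


def grynkiewicz_ca(r, calib: CalciumCalibration):
    """Free-calcium concentration (nM) from a Fura-2 ratio.

    Strictly increasing in R on [Rmin, Rmax); R = Rmin gives 0 and the ratio
    midpoint gives exactly Kd * beta.  R >= Rmax (saturation) and R < Rmin
    raise :class:`CalibrationError`.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr < calib.rmin):
        raise CalibrationError(f"ratio below Rmin={calib.rmin}: no valid concentration")
    if np.any(arr >= calib.rmax):
        raise CalibrationError(f"ratio at or above Rmax={calib.rmax}: dye saturated")
    ca = calib.kd * calib.beta * (arr - calib.rmin) / (calib.rmax - arr)
    return float(ca) if np.ndim(r) == 0 else ca


def fccp_peak_percent(basal_ca: float, peak_ca: float) -> float:
    """Percentage difference of the post-FCCP calcium peak over baseline."""
    if basal_ca <= 0:
        raise DataError(f"basal [Ca2+] must be > 0, got {basal_ca}")
    return 100.0 * (peak_ca - basal_ca) / basal_ca


@dataclass
class OCRTrace:
    """One well's OCR time course with the three injection marks.

    ``oligomycin_idx``, ``fccp_idx`` and ``antimycin_idx`` are the indices of
    the first measurement *after* the respective injection; they must be
    strictly increasing and leave at least one measurement per segment.
    """

    timepoints: np.ndarray
    ocr: np.ndarray
    oligomycin_idx: int
    fccp_idx: int
    antimycin_idx: int

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        if self.timepoints.shape != self.ocr.shape:
            raise TraceError("trace: timepoints and ocr lengths differ")
        if np.any(np.diff(self.timepoints) <= 0):
            raise TraceError("trace: timepoints must be strictly increasing")
        n = len(self.ocr)
        if not (0 < self.oligomycin_idx < self.fccp_idx < self.antimycin_idx < n):
            raise TraceError(
                "trace: injections must be ordered oligomycin < FCCP < "
                "antimycin/rotenone with >=1 measurement per segment"
            )

    @classmethod
    def from_phases(cls, timepoints, ocr, phases) -> "OCRTrace":
        """Build a trace from a per-measurement phase label column."""
        phases = list(phases)
        for ph in phases:
            if ph not in PHASES:
                raise TraceError(f"trace: unknown phase {ph!r}; expected one of {PHASES}")
        try:
            idx = [phases.index(ph) for ph in PHASES[1:]]
        except ValueError as exc:
            raise TraceError(f"trace: missing phase segment ({exc})") from exc
        if [PHASES.index(p) for p in phases] != sorted(PHASES.index(p) for p in phases):
            raise TraceError("trace: phases out of order")
        return cls(timepoints, ocr, *idx)

    def segment(self, name: str) -> np.ndarray:
        bounds = {
            "baseline": (0, self.oligomycin_idx),
            "oligomycin": (self.oligomycin_idx, self.fccp_idx),
            "fccp": (self.fccp_idx, self.antimycin_idx),
            "antimycin_rotenone": (self.antimycin_idx, len(self.ocr)),
        }
        lo, hi = bounds[name]
        return self.ocr[lo:hi]


@dataclass
class RespirationIndices:
    """Mito Stress respiratory indices, all in the trace's OCR units."""

    non_mito: float
    basal: float
    atp_linked: float
    maximal: float
    spare: float

    def as_dict(self) -> dict[str, float]:
        return {
            "non_mito": self.non_mito,
            "basal": self.basal,
            "atp_linked": self.atp_linked,
            "maximal": self.maximal,
            "spare": self.spare,
        }


def ocr_indices(trace: OCRTrace, reading: str = "last") -> RespirationIndices:
    """Compute Mito Stress respiratory indices from one trace.

    ``reading="last"`` (default) uses the last pre-oligomycin measurement,
    the minimum post-oligomycin and the maximum post-FCCP reading;
    ``reading="mean"`` uses segment means throughout.
    """
    base = trace.segment("baseline")
    oligo = trace.segment("oligomycin")
    fccp = trace.segment("fccp")
    aarot = trace.segment("antimycin_rotenone")
    non_mito = float(aarot.mean())
    if reading == "last":
        pre = float(base[-1])
        post_oligo = float(oligo.min())
        post_fccp = float(fccp.max())
    elif reading == "mean":
        pre = float(base.mean())
        post_oligo = float(oligo.mean())
        post_fccp = float(fccp.mean())
    else:
        raise DataError(f"reading: {reading!r} not in ('last', 'mean')")
    basal = pre - non_mito
    atp_linked = pre - post_oligo
    maximal = post_fccp - non_mito
    return RespirationIndices(
        non_mito=non_mito,
        basal=basal,
        atp_linked=atp_linked,
        maximal=maximal,
        spare=maximal - basal,
    )


def percent_of_control(values, control_values):
    """Express values as a percentage of the control-group mean (== 100)."""
    control = np.asarray(control_values, dtype=float)
    mean_ctrl = control.mean()
    if not np.isfinite(mean_ctrl) or mean_ctrl <= 0:
        raise DataError(f"control mean must be > 0, got {mean_ctrl}")
    return 100.0 * np.asarray(values, dtype=float) / mean_ctrl


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------


def read_ocr_table(path: str | Path) -> dict[str, OCRTrace]:
    """Read a per-well OCR TSV with columns time, well, ocr, phase."""
    df = pd.read_csv(path, sep="\t")
    need = {"time", "well", "ocr", "phase"}
    if not need <= set(df.columns):
        raise DataError(f"{path}: OCR table needs columns {sorted(need)}")
    traces: dict[str, OCRTrace] = {}
    for well, sub in df.groupby("well", sort=True):
        sub = sub.sort_values("time")
        traces[str(well)] = OCRTrace.from_phases(
            sub["time"].to_numpy(), sub["ocr"].to_numpy(), sub["phase"].tolist()
        )
    return traces


def ocr_indices_table(traces: dict[str, OCRTrace], reading: str = "last") -> pd.DataFrame:
    """Per-well respiratory index table."""
    rows = []
    for well, trace in traces.items():
        rows.append({"well": well, **ocr_indices(trace, reading=reading).as_dict()})
    return pd.DataFrame(rows)


def read_calcium_table(path: str | Path) -> tuple[CalciumCalibration, pd.DataFrame]:
    """Read a Fura-2 ratio TSV with a ``# key = value`` calibration header.

    Recognized header keys: rmin, rmax, beta, kd.  The body has columns
    cell_id and R.
    """
    header: dict[str, float] = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line.lstrip("#").partition("=")
                header[key.strip().lower()] = float(value)
            else:
                body.append(line)
    if not {"rmin", "rmax"} <= set(header):
        raise DataError(f"{path}: calibration header must define rmin and rmax")
    calib = CalciumCalibration(
        rmin=header["rmin"],
        rmax=header["rmax"],
        beta=header.get("beta"),
        kd=header.get("kd", FURA2_KD_NM),
    )
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), sep="\t")
    if not {"cell_id", "R"} <= set(df.columns):
        raise DataError(f"{path}: calcium table needs cell_id and R columns")
    return calib, df


def calcium_table(calib: CalciumCalibration, ratios: pd.DataFrame) -> pd.DataFrame:
    """Append a calibrated [Ca2+] (nM) column to a cell_id/R table."""
    out = ratios.copy()
    out["ca_nm"] = grynkiewicz_ca(out["R"].to_numpy(), calib)
    return out
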