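"""Smaller quantitative readouts feeding the same curve-fitting machinery.

Methylation-state dose response (methylated/unmethylated intensity
ratios re-normalized to vehicle), relative qPCR quantification by the
2^-ddCq method, and phenotype normalization (confluency, cytotoxicity
corrected for confluency, metabolic activity — each relative to the
vehicle mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .curves import RatioSeries

__all__ = [
    "QpcrMeasurement",
    "read_cq_table",
    "methylation_series",
    "ddcq_fold_change",
    "normalize_phenotype",
]


def read_cq_table(path) -> "pd.DataFrame":
    """Read a qPCR Cq table: TSV with sample_id, amplicon_id, role, cq.

    Technical replicates (repeated sample x amplicon rows) are averaged
    on the Cq scale; roles must be "target" or "reference".
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "amplicon_id", "role", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    bad_roles = set(df["role"]) - {"target", "reference"}
    if bad_roles:
        raise ValueError(f"unknown roles: {sorted(bad_roles)}")
    if (df["cq"] <= 0).any() or df["cq"].isna().any():
        raise ValueError("Cq values must be positive and present")
    return (df.groupby(["sample_id", "amplicon_id", "role"], as_index=False)
            ["cq"].mean())


@dataclass(frozen=True)
class QpcrMeasurement:
    """Mean quantification cycle of one amplicon in one sample."""

    sample_id: str
    amplicon_id: str
    cq: float                    # mean over technical replicates, cycles
    role: str = "target"         # "target" or "reference"

    def __post_init__(self) -> None:
        if not np.isfinite(self.cq) or self.cq <= 0:
            raise ValueError(
                f"invalid Cq for {self.sample_id}/{self.amplicon_id}: {self.cq}")


def _ratio(mod, unmod) -> np.ndarray:
    mod = np.asarray(mod, dtype=float)
    unmod = np.asarray(unmod, dtype=float)
    out = np.full(mod.shape, np.nan)
    ok = np.isfinite(mod) & np.isfinite(unmod) & (unmod > 0)
    out[ok] = mod[ok] / unmod[ok]
    return out


def methylation_series(mod_intensities: Sequence[float],
                       unmod_intensities: Sequence[float],
                       doses_nM: Sequence[float],
                       vehicle_mod: Sequence[float],
                       vehicle_unmod: Sequence[float]) -> RatioSeries:
    """Vehicle-normalized methylated:unmethylated intensity ratios per dose.

    A dose point is missing (never infinite) when either member of the
    pair is absent or the unmethylated intensity is zero; the vehicle
    reference is the mean of the per-replicate vehicle ratios.
    """
    doses = np.asarray(doses_nM, dtype=float)
    dose_ratio = _ratio(mod_intensities, unmod_intensities)
    veh_ratio = _ratio(vehicle_mod, vehicle_unmod)
    veh_ratio = veh_ratio[np.isfinite(veh_ratio)]
    x = np.log10(doses)
    if veh_ratio.size == 0:
        return RatioSeries(x=x, y=np.full(doses.shape, np.nan),
                           n_vehicle=0, fittable=False)
    ref = float(veh_ratio.mean())
    return RatioSeries(x=x, y=dose_ratio / ref, n_vehicle=int(veh_ratio.size))


def _mean_cq(value) -> float:
    if isinstance(value, QpcrMeasurement):
        return value.cq
    arr = np.asarray(value, dtype=float).ravel()
    return float(arr.mean())


def ddcq_fold_change(target_treated, reference_treated,
                     target_control, reference_control) -> float:
    """Relative expression by the 2^-ddCq method.

    FC = 2^-[(Cq_tgt,treated - Cq_ref,treated)
             - (Cq_tgt,control - Cq_ref,control)].
    Each argument is a Cq value, a :class:`QpcrMeasurement`, or a sequence
    of reference Cqs (averaged, i.e. a geometric mean on the expression
    scale).  Also computes transcript-form ratios, e.g. truncated versus
    full-length, by passing the two amplicons as target and reference.
    """
    names = ("target_treated", "reference_treated",
             "target_control", "reference_control")
    vals = []
    for name, v in zip(names, (target_treated, reference_treated,
                               target_control, reference_control)):
        try:
            cq = _mean_cq(v)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"unreadable Cq for {name}: {v!r}") from exc
        if not np.isfinite(cq):
            raise ValueError(f"missing Cq for {name}")
        vals.append(cq)
    ddcq = (vals[0] - vals[1]) - (vals[2] - vals[3])
    return float(2.0 ** (-ddcq))


def _normalize(values: np.ndarray, vehicle: np.ndarray) -> np.ndarray:
    veh = vehicle[np.isfinite(vehicle)]
    if veh.size == 0:
        raise ValueError("no vehicle values to normalize against")
    return values / float(veh.mean())


def normalize_phenotype(confluency: Sequence[float],
                        cytotoxicity: Sequence[float],
                        metabolic: Sequence[float],
                        vehicle_confluency: Sequence[float],
                        vehicle_cytotoxicity: Sequence[float],
                        vehicle_metabolic: Sequence[float],
                        ) -> dict[str, np.ndarray]:
    """Vehicle-normalized phenotype series, ready for curve fitting.

    Cytotoxicity is divided by confluency point-by-point first (cell-death
    signal per amount of cells) in both treated and vehicle wells;
    confluency and metabolic activity are normalized without correction.
    Non-positive confluency invalidates the corrected point.
    """
    conf = np.asarray(confluency, dtype=float)
    cyto = np.asarray(cytotoxicity, dtype=float)
    met = np.asarray(metabolic, dtype=float)
    vconf = np.asarray(vehicle_confluency, dtype=float)
    vcyto = np.asarray(vehicle_cytotoxicity, dtype=float)
    vmet = np.asarray(vehicle_metabolic, dtype=float)

    corrected = np.where(conf > 0, cyto / np.where(conf > 0, conf, np.nan),
                         np.nan)
    v_corrected = np.where(vconf > 0,
                           vcyto / np.where(vconf > 0, vconf, np.nan), np.nan)
    return {
        "confluency": _normalize(conf, vconf),
        "cytotoxicity": _normalize(corrected, v_corrected),
        "metabolic": _normalize(met, vmet),
    }
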