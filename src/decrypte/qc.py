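"""Replicate QC and the target-coverage-versus-depth simulation.

Three precision readouts: a null split test of the pooled vehicle
(DMSO) controls into two random halves with a per-protein Student t-test;
the coefficient of variation across the five dose measurements, compared
between regulated and unregulated curves; and the standard deviation of
pEC50 across replicate screens for concordantly regulated proteins.
Coverage: proteins ranked by mean vehicle iBAQ simulate shallower
proteomes and each drug's designated-target recovery is traced over depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DrugTable, IntensityTable

__all__ = [
    "median_center",
    "dmso_split_test",
    "cov_by_regulation",
    "pec50_reproducibility",
    "target_coverage_curve",
    "SplitTestResult",
    "CoverageResult",
]


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample median-centering normalization.

    Each column is rescaled so its median matches the grand median of all
    column medians — multiplicative centering, which keeps intensities
    positive (equivalent to subtracting medians in log space).
    """
    med = matrix.median(axis=0, skipna=True)
    target = float(np.nanmedian(med.to_numpy()))
    return matrix.mul(target / med, axis=1)


@dataclass
class SplitTestResult:
    stats: pd.DataFrame        # protein_id, t, p, q
    group_a: list[str]
    group_b: list[str]
    n_complete: int
    n_excluded: int            # zero-variance-in-both-groups proteins

    def fraction_significant(self, q_cutoff: float = 0.05) -> float:
        if self.stats.empty:
            return 0.0
        return float((self.stats["q"] < q_cutoff).mean())


def dmso_split_test(vehicle: pd.DataFrame, seed: int = 0) -> SplitTestResult:
    """Random half-vs-half t-test of the pooled vehicle controls.

    The columns are median-centered, complete-case proteins are kept, the
    samples are randomly assigned into two equal groups (seeded) and a
    classical two-sided two-sample Student t-test is run per protein,
    Benjamini-Hochberg adjusted.  A well-behaved null assay should yield
    almost no q < 0.05 discoveries.
    """
    n_cols = vehicle.shape[1]
    if n_cols % 2 != 0:
        raise ValueError("need an even number of vehicle columns")
    centered = median_center(vehicle)
    complete = centered.dropna(axis=0, how="any")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_cols)
    cols = list(complete.columns)
    group_a = [cols[i] for i in sorted(perm[: n_cols // 2])]
    group_b = [cols[i] for i in sorted(perm[n_cols // 2:])]

    a = complete[group_a].to_numpy(dtype=float)
    b = complete[group_b].to_numpy(dtype=float)
    with warnings.catch_warnings():
        # constant proteins trigger a precision warning; they are excluded
        # from the result and counted below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    valid = np.isfinite(p)
    df = pd.DataFrame({
        "protein_id": complete.index[valid],
        "t": t[valid],
        "p": p[valid],
    })
    if not df.empty:
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q"] = []
    return SplitTestResult(stats=df.reset_index(drop=True),
                           group_a=group_a, group_b=group_b,
                           n_complete=len(complete),
                           n_excluded=int((~valid).sum()))


def cov_by_regulation(table: IntensityTable, calls: pd.DataFrame,
                      label_col: str = "final_label",
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """CoV across the five dose measurements, split by regulation status.

    Intensities are median-centered per sample first; the CoV (sample
    sd / mean) treats the five doses of one drug as pseudo-replicates, so
    truly regulated proteins show systematically higher CoV.  Returns the
    per-curve records and the median CoV per group ("regulated" pools up
    and down).
    """
    centered = median_center(table.intensities)
    records = []
    for drug in table.drug_ids():
        dose_cols, _ = table.plate_columns(drug)
        sub = centered[dose_cols]
        vals = sub.to_numpy(dtype=float)
        ok = np.isfinite(vals)
        n_ok = ok.sum(axis=1)
        vz = np.where(ok, vals, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = vz.sum(axis=1) / n_ok
            ss = (np.where(ok, vz - mean[:, None], 0.0) ** 2).sum(axis=1)
            sd = np.sqrt(ss / np.maximum(n_ok - 1, 1))
            cov = np.where((n_ok >= 2) & (mean > 0), sd / mean, np.nan)
        records.append(pd.DataFrame({
            "drug_id": drug,
            "protein_id": table.protein_ids,
            "cov": cov,
        }))
    recs = pd.concat(records, ignore_index=True).dropna(subset=["cov"])
    merged = recs.merge(calls[["drug_id", "protein_id", label_col]],
                        on=["drug_id", "protein_id"], how="left")
    merged["regulation"] = np.where(
        merged[label_col].isin(["up", "down"]), "regulated", "unregulated")
    summaries = merged.groupby("regulation")["cov"].median()
    return merged.drop(columns=[label_col]), summaries


def pec50_reproducibility(replicate_calls: pd.DataFrame,
                          min_support: int = 3, n_replicates: int = 4,
                          label_col: str = "final_label",
                          ) -> tuple[pd.DataFrame, int]:
    """Per drug x protein sd of pEC50 across concordant replicate screens.

    Qualifying entries are regulated (up or down) in at least
    ``min_support`` of ``n_replicates`` replicates; replicate sets with
    discordant directions are excluded and counted.
    """
    required = {"drug_id", "protein_id", "replicate", label_col, "pec50"}
    missing = required - set(replicate_calls.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    reg = replicate_calls[replicate_calls[label_col].isin(["up", "down"])]
    rows = []
    n_discordant = 0
    for (drug, prot), grp in reg.groupby(["drug_id", "protein_id"], sort=True):
        if len(grp) < min_support:
            continue
        directions = set(grp[label_col])
        if len(directions) > 1:
            n_discordant += 1
            continue
        rows.append((drug, prot, directions.pop(), len(grp),
                     float(grp["pec50"].std(ddof=1))))
    out = pd.DataFrame(rows, columns=["drug_id", "protein_id", "direction",
                                      "n_support", "pec50_sd"])
    return out, n_discordant


@dataclass
class CoverageResult:
    curve: pd.DataFrame            # depth x drug fraction of targets covered
    any_target: pd.Series          # per depth: fraction of drugs with >=1 target
    n_drugs_without_targets: int


def target_coverage_curve(mean_ibaq: pd.Series,
                          drug_targets: Mapping[str, Set[str]] | DrugTable,
                          depths: Sequence[int]) -> CoverageResult:
    """Designated-target recovery as the proteome is cut at depth ranks.

    Proteins are ranked by mean vehicle iBAQ descending (ties broken by
    protein id, deterministically); at each depth cutoff the fraction of
    each drug's targets inside the head of the list is recorded, plus the
    fraction of drugs retaining at least one detected target.
    """
    if isinstance(drug_targets, DrugTable):
        drug_targets = {d: set(drug_targets.targets_of(d))
                        for d in drug_targets.drugs.index}
    ranked = (mean_ibaq.dropna()
              .rename_axis("protein_id").reset_index(name="ibaq")
              .sort_values(["ibaq", "protein_id"],
                           ascending=[False, True], kind="mergesort"))
    ordered = ranked["protein_id"].to_list()
    depths = sorted(int(d) for d in depths)
    usable = {d: t for d, t in drug_targets.items() if t}
    n_empty = len(drug_targets) - len(usable)
    cov_rows = {}
    any_rows = {}
    for depth in depths:
        head = set(ordered[:depth])
        fracs = {d: len(t & head) / len(t) for d, t in usable.items()}
        cov_rows[depth] = fracs
        any_rows[depth] = (np.mean([f > 0 for f in fracs.values()])
                           if fracs else np.nan)
    curve = pd.DataFrame.from_dict(cov_rows, orient="index").sort_index()
    curve.index.name = "depth"
    curve = curve[sorted(curve.columns)]
    return CoverageResult(curve=curve,
                          any_target=pd.Series(any_rows, name="any_target"),
                          n_drugs_without_targets=n_empty)
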