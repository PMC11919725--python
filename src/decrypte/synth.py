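"""Synthetic drug-screen generator.

Emulates an expression-proteomics screen of D drugs x P proteins at five
doses (1 nM - 10 uM in full log10 steps) plus DMSO vehicle controls: most
proteins are unregulated, a small fraction follows sigmoidal up- or
down-regulation, and measured LFQ intensities carry multiplicative
log-normal noise calibrated to a target coefficient of variation.
Each generated curve comes with a ground-truth record (label plus
generating parameters) so that fitting, classification, filtering and
enrichment can be scored against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .curves import llogistic4
from .io import AnnotationMap, DrugTable, IntensityTable, format_sample_key

__all__ = [
    "SynthConfig",
    "ScreenData",
    "sample_curve_params",
    "generate_screen",
    "generate_annotation",
    "generate_drug_table",
]

LOG2_MIN_EFFECT = math.log2(1.5)


@dataclass(frozen=True)
class SynthConfig:
    """Study design of one synthetic screen.

    The defaults encode the assumed screen conditions: five full-log10
    doses from 1 nM to 10 uM, three vehicle controls per drug plate plus
    a pooled 48-sample vehicle matrix, ~6.5% up- and ~6.9% down-regulated
    curves (86.6% unchanged), and 19% CoV multiplicative noise.
    """

    n_drugs: int = 10
    n_proteins: int = 2000
    doses_nM: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0, 10000.0)
    n_vehicle_per_plate: int = 3
    n_vehicle_total: int = 48
    frac_up: float = 0.065
    frac_down: float = 0.069
    noise_cov: float = 0.19
    missing_rate: float = 0.05
    min_effect: float = 1.5           # smallest |fold change| of regulated curves
    effect_log2_median: float = 1.0   # median |log2 FC| before truncation (2-fold)
    effect_log2_sigma: float = 0.5    # spread of |log2 FC| (log-normal)
    slope_range: tuple[float, float] = (0.5, 3.0)
    x0_range: tuple[float, float] = (-1.0, 5.0)  # log10(nM), extends past range
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_up", "frac_down", "noise_cov", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_up + self.frac_down >= 1.0:
            raise ValueError("frac_up + frac_down must be < 1")
        doses = np.asarray(self.doses_nM, dtype=float)
        if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be positive and strictly increasing")
        if self.min_effect <= 1.0:
            raise ValueError("min_effect must exceed 1")

    @property
    def log_doses(self) -> np.ndarray:
        return np.log10(np.asarray(self.doses_nM, dtype=float))

    @property
    def frac_not(self) -> float:
        return 1.0 - self.frac_up - self.frac_down


@dataclass
class ScreenData:
    """Everything one synthetic screen produces."""

    config: SynthConfig
    table: IntensityTable          # plate intensities + peptide counts + iBAQ
    vehicle_pool: pd.DataFrame     # proteins x n_vehicle_total null samples
    truth: pd.DataFrame            # one row per drug x protein
    baseline: pd.Series            # true underlying abundance per protein


def _noise_sigma(cov: float) -> float:
    """Log-normal sigma with CoV = sqrt(exp(sigma^2) - 1) = cov."""
    return math.sqrt(math.log1p(cov * cov))


def _multiplicative_noise(rng: np.random.Generator, cov: float, size) -> np.ndarray:
    if cov == 0.0:
        return np.ones(size)
    sigma = _noise_sigma(cov)
    # mean-1 multiplicative noise: mu = -sigma^2/2
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def sample_curve_params(label: str, rng: np.random.Generator,
                        config: Optional[SynthConfig] = None) -> dict:
    """Draw ground-truth curve parameters for one label.

    Regulated curves have t = 1 and plateau ratio ``true_effect`` = b/t
    with |log2 effect| log-normally distributed and truncated below at
    log2(min_effect); slope and inflection are uniform over their ranges.
    Unregulated curves are flat at ratio 1.
    """
    cfg = config or SynthConfig()
    if label == "not":
        return dict(true_label="not", true_t=1.0, true_b=1.0, true_s=0.0,
                    true_x0=0.5 * sum(cfg.x0_range), true_effect=1.0)
    if label not in ("up", "down"):
        raise ValueError(f"unknown label {label!r}")
    lo = math.log2(cfg.min_effect)
    mu = math.log(cfg.effect_log2_median)
    l2 = 0.0
    for _ in range(1000):
        l2 = rng.lognormal(mean=mu, sigma=cfg.effect_log2_sigma)
        if l2 >= lo:
            break
    else:  # pragma: no cover - truncation region is wide
        l2 = lo
    effect = 2.0 ** l2 if label == "up" else 2.0 ** (-l2)
    s = rng.uniform(*cfg.slope_range)
    x0 = rng.uniform(*cfg.x0_range)
    return dict(true_label=label, true_t=1.0, true_b=effect, true_s=s,
                true_x0=x0, true_effect=effect)


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(n)]


def _drug_ids(n: int) -> list[str]:
    return [f"D{i:03d}" for i in range(n)]


def generate_screen(config: SynthConfig) -> ScreenData:
    """Generate one full screen: plates, pooled vehicles, truth table.

    Baseline abundances are log-uniform over five orders of magnitude;
    observed unique-peptide counts rise with abundance; missing values
    are injected preferentially at low abundance (left-censoring).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    P, D = cfg.n_proteins, cfg.n_drugs
    proteins = _protein_ids(P)
    drugs = _drug_ids(D)
    x = cfg.log_doses
    n_dose = x.size

    # true abundance, log-uniform over >= 5 orders of magnitude
    baseline = 10.0 ** rng.uniform(4.5, 9.5, size=P)
    n_theoretical = np.clip(np.round(3 + 57 * (np.log10(baseline) - 4.5) / 5.0
                                     * rng.uniform(0.5, 1.5, size=P)),
                            1, 80).astype(int)
    # peptide-count intensity scaling: more abundant -> more peptides seen
    pep_lambda = 1.0 + 25.0 * (np.log10(baseline) - 4.5) / 5.0

    # per-protein missingness, decaying with abundance rank
    order = np.argsort(np.argsort(baseline))  # rank 0 = least abundant
    pct = order / max(P - 1, 1)
    p_miss = np.clip(2.0 * cfg.missing_rate * (1.0 - pct), 0.0, 1.0)

    labels = rng.choice(np.array(["up", "down", "not"]), size=(D, P),
                        p=[cfg.frac_up, cfg.frac_down, cfg.frac_not])

    truth_rows = []
    inten_cols: dict[str, np.ndarray] = {}
    pep_cols: dict[str, np.ndarray] = {}

    for d_i, drug in enumerate(drugs):
        params = np.empty((P, 4))
        for p_i in range(P):
            rec = sample_curve_params(labels[d_i, p_i], rng, cfg)
            params[p_i] = (rec["true_t"], rec["true_b"],
                           rec["true_s"], rec["true_x0"])
            truth_rows.append((drug, proteins[p_i], rec["true_label"],
                               rec["true_t"], rec["true_b"], rec["true_s"],
                               rec["true_x0"], rec["true_effect"]))
        t, b, s, x0 = params.T
        # true ratio at each dose (P x n_dose)
        ratio = llogistic4(x[None, :], t[:, None], b[:, None],
                           s[:, None], x0[:, None])
        noise = _multiplicative_noise(rng, cfg.noise_cov, (P, n_dose))
        dose_inten = baseline[:, None] * ratio * noise
        miss = rng.random((P, n_dose)) < p_miss[:, None]
        dose_inten[miss] = np.nan
        for j, dose in enumerate(cfg.doses_nM):
            key = format_sample_key(drug, dose, 1)
            inten_cols[key] = dose_inten[:, j]
            npep = np.minimum(n_theoretical,
                              1 + rng.poisson(pep_lambda)).astype(float)
            npep[miss[:, j]] = np.nan
            pep_cols[key] = npep
        for r in range(cfg.n_vehicle_per_plate):
            key = format_sample_key(drug, 0, r + 1)
            veh = baseline * _multiplicative_noise(rng, cfg.noise_cov, P)
            veh[rng.random(P) < p_miss] = np.nan
            inten_cols[key] = veh
            npep = np.minimum(n_theoretical,
                              1 + rng.poisson(pep_lambda)).astype(float)
            npep[np.isnan(veh)] = np.nan
            pep_cols[key] = npep

    # pooled null vehicle matrix (split-test design) + per-sample iBAQ
    pool_cols = {}
    ibaq_cols = {}
    for r in range(cfg.n_vehicle_total):
        key = format_sample_key("VEH", 0, r + 1)
        veh = baseline * _multiplicative_noise(rng, cfg.noise_cov, P)
        veh[rng.random(P) < p_miss] = np.nan
        pool_cols[key] = veh
        ibaq_cols[key] = veh / n_theoretical

    idx = pd.Index(proteins, name="protein_id")
    table = IntensityTable(
        intensities=pd.DataFrame(inten_cols, index=idx),
        peptide_counts=pd.DataFrame(pep_cols, index=idx),
        ibaq=pd.DataFrame(ibaq_cols, index=idx),
    )
    truth = pd.DataFrame(truth_rows, columns=[
        "drug_id", "protein_id", "true_label", "true_t", "true_b",
        "true_s", "true_x0", "true_effect"])
    return ScreenData(config=cfg, table=table,
                      vehicle_pool=pd.DataFrame(pool_cols, index=idx),
                      truth=truth,
                      baseline=pd.Series(baseline, index=idx, name="baseline"))


def generate_annotation(universe: Sequence[str], n_terms: int,
                        rng: np.random.Generator,
                        size_range: tuple[int, int] = (5, 200),
                        planted: Optional[Mapping[str, Sequence[str]]] = None,
                        ) -> AnnotationMap:
    """Random flat gene-set annotation over ``universe``.

    Term sizes are log-uniform over ``size_range``; ``planted`` adds
    terms with the given member sets verbatim (for recoverable enrichment
    signal, e.g. most of one drug's true up-set).
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty universe")
    if n_terms < 0:
        raise ValueError("n_terms must be >= 0")
    lo, hi = size_range
    hi = min(hi, len(universe))
    terms: dict[str, frozenset[str]] = {}
    arr = np.array(universe)
    for i in range(n_terms):
        size = int(round(10.0 ** rng.uniform(math.log10(max(lo, 1)),
                                             math.log10(max(hi, 1)))))
        size = int(np.clip(size, 1, len(universe)))
        members = rng.choice(arr, size=size, replace=False)
        terms[f"T{i:04d}"] = frozenset(members.tolist())
    for name, members in (planted or {}).items():
        extra = frozenset(members)
        if not extra <= set(universe):
            raise ValueError(f"planted term {name!r} has ids outside universe")
        terms[name] = extra
    return AnnotationMap(terms=terms, universe=frozenset(universe))


def generate_drug_table(screen: ScreenData, rng: np.random.Generator,
                        n_targets_range: tuple[int, int] = (1, 5)) -> DrugTable:
    """Assign each drug designated targets, biased toward its regulated set."""
    rows = {}
    truth = screen.truth
    all_proteins = np.array(screen.table.protein_ids)
    for drug in sorted(truth.drug_id.unique()):
        reg = truth[(truth.drug_id == drug) & (truth.true_label != "not")]
        k = int(rng.integers(n_targets_range[0], n_targets_range[1] + 1))
        pool = reg.protein_id.to_numpy()
        if pool.size >= k:
            targets = rng.choice(pool, size=k, replace=False)
        else:
            extra = rng.choice(all_proteins, size=k - pool.size, replace=False)
            targets = np.concatenate([pool, extra])
        rows[drug] = (tuple(sorted(targets)), "synthetic")
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["targets", "drug_class"])
    df.index.name = "drug_id"
    return DrugTable(drugs=df)
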