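"""End-to-end orchestration: simulate -> fit -> classify -> filter ->
enrich -> qc, under one config with a single fanned-out seed and a run
manifest that accounts for every curve at every stage boundary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import classify as _classify
from . import enrichment as _enrich
from . import qc as _qc
from .curves import curve_metrics, fit_llogistic4, normalize_to_vehicle
from .io import (IntensityTable, read_keyvalue_config, write_annotation,
                 write_calls_per_class, write_table)
from .synth import (ScreenData, SynthConfig, generate_annotation,
                    generate_drug_table, generate_screen)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "stage_seeds",
    "fit_screen",
    "run_pipeline",
]

log = logging.getLogger("decrypte.pipeline")

STAGES = ("simulate", "fit", "train", "classify", "enrich", "qc")

CURVE_COLUMNS = [
    "drug_id", "protein_id", "t", "b", "s", "x0", "pec50", "converged",
    "fittable", "n_points", "auc", "r2", "mad", "curve_fold_change",
    "linear_slope",
    "rel_int_1", "rel_int_2", "rel_int_3", "rel_int_4", "rel_int_5",
    "n_pep_1", "n_pep_2", "n_pep_3", "n_pep_4", "n_pep_5",
]


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds spawned from one global seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] & 0x7FFFFFFF)
            for name, c in zip(STAGES, children)}


@dataclass(frozen=True)
class PipelineConfig:
    """One run's configuration: screen design plus downstream knobs."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    n_terms: int = 150
    n_trees: int = _classify.N_TREES
    train_frac: float = 0.8
    plant_terms: bool = True

    _SYNTH_KEYS = ("n_drugs", "n_proteins", "n_vehicle_per_plate",
                   "n_vehicle_total", "seed")
    _SYNTH_FLOATS = ("frac_up", "frac_down", "noise_cov", "missing_rate",
                     "min_effect", "effect_log2_median", "effect_log2_sigma")

    @classmethod
    def from_keyvalues(cls, values: dict[str, str]) -> "PipelineConfig":
        synth_kwargs: dict = {}
        own_kwargs: dict = {}
        for key, raw in values.items():
            if key in cls._SYNTH_KEYS:
                synth_kwargs[key] = int(raw)
            elif key in cls._SYNTH_FLOATS:
                synth_kwargs[key] = float(raw)
            elif key == "doses_nM":
                synth_kwargs[key] = tuple(float(v) for v in raw.split(","))
            elif key in ("n_terms", "n_trees"):
                own_kwargs[key] = int(raw)
            elif key == "train_frac":
                own_kwargs[key] = float(raw)
            elif key == "plant_terms":
                own_kwargs[key] = raw.strip().lower() in ("1", "true", "yes")
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(synth=SynthConfig(**synth_kwargs), **own_kwargs)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls.from_keyvalues(read_keyvalue_config(path))

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    seeds: dict[str, int]
    paths: dict[str, str]
    counts: dict[str, int]

    def validate(self) -> None:
        c = self.counts
        for stage in ("classified", "final"):
            total = sum(c[f"{stage}_{lbl}"] for lbl in ("up", "down", "not"))
            if total != c["curves_total"]:
                raise ValueError(
                    f"{stage} counts sum to {total}, expected "
                    f"{c['curves_total']}")

    def write(self, path) -> None:
        self.validate()
        Path(path).write_text(json.dumps(asdict(self), sort_keys=True,
                                         indent=1) + "\n")


def fit_screen(table: IntensityTable) -> pd.DataFrame:
    """Fit every protein x drug curve of a screen.

    Returns one row per curve with the four model parameters, pEC50, the
    descriptive metrics and the per-dose relative intensities and
    unique-peptide counts consumed by the classifier.
    """
    from .curves import curve_metrics_batch, fit_llogistic4_batch

    frames = []
    proteins = list(table.protein_ids)
    for drug in table.drug_ids():
        dose_cols, veh_cols = table.plate_columns(drug)
        doses = table.samples.loc[dose_cols, "dose_nM"].to_numpy(dtype=float)
        x = np.log10(doses)
        inten = table.intensities[dose_cols].to_numpy(dtype=float)
        veh = table.intensities[veh_cols].to_numpy(dtype=float)
        if table.peptide_counts is not None:
            peps = table.peptide_counts[dose_cols].to_numpy(dtype=float)
        else:
            peps = np.full_like(inten, np.nan)
        veh_ok = np.isfinite(veh)
        n_veh = veh_ok.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            veh_mean = np.where(veh_ok, veh, 0.0).sum(axis=1) / n_veh
        ratios = inten / veh_mean[:, None]
        # a protein with no quantified vehicle value has no reference
        ratios[~np.isfinite(veh_mean)] = np.nan

        fits = fit_llogistic4_batch(x, ratios)
        mets = curve_metrics_batch(x, ratios, fits)
        block = pd.DataFrame({"drug_id": drug, "protein_id": proteins})
        block = pd.concat([block, fits[["t", "b", "s", "x0", "pec50",
                                        "converged", "fittable",
                                        "n_points"]].reset_index(drop=True),
                           mets.reset_index(drop=True)], axis=1)
        for i in range(len(doses)):
            block[f"rel_int_{i + 1}"] = ratios[:, i]
            block[f"n_pep_{i + 1}"] = peps[:, i]
        frames.append(block)
    return pd.concat(frames, ignore_index=True)[CURVE_COLUMNS]


def _planted_terms(screen: ScreenData, rng: np.random.Generator,
                   coverage: float = 0.8, max_planted: int = 8) -> dict:
    """Terms seeded with most of a drug's true up-set, to give the
    enrichment stage recoverable structure."""
    planted = {}
    for drug in sorted(screen.truth.drug_id.unique())[:max_planted]:
        up = screen.truth.query(
            "drug_id == @drug and true_label == 'up'")["protein_id"].to_numpy()
        k = int(round(coverage * up.size))
        if k < 5:
            continue
        planted[f"PLANT_{drug}"] = sorted(
            rng.choice(up, size=k, replace=False).tolist())
    return planted


def run_pipeline(config: PipelineConfig | str | Path, out_dir,
                 seed: Optional[int] = None) -> RunManifest:
    """Execute all stages and write every artifact under ``out_dir``.

    ``seed`` overrides the config's; reruns with the same config and seed
    are byte-identical.  Stage failures abort with the stage name in the
    exception message.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    if seed is None:
        seed = config.synth.seed
    else:
        config = replace(config, synth=replace(config.synth, seed=seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)
    paths: dict[str, str] = {}
    counts: dict[str, int] = {}

    def _stage(name):
        log.info("stage %s", name)
        return np.random.default_rng(seeds[name])

    # -- simulate ----------------------------------------------------------
    try:
        _stage("simulate")
        screen = generate_screen(replace(config.synth, seed=seeds["simulate"]))
        write_table(screen.truth, out / "truth.tsv")
        screen.table.intensities.rename_axis("protein_id").reset_index().pipe(
            write_table, out / "intensities.tsv", sort_by=["protein_id"])
        paths["truth"] = "truth.tsv"
        paths["intensities"] = "intensities.tsv"
    except Exception as exc:
        raise RuntimeError(f"stage simulate failed: {exc}") from exc

    # -- fit ---------------------------------------------------------------
    try:
        _stage("fit")
        curves = fit_screen(screen.table)
        write_table(curves, out / "curves.tsv")
        paths["curves"] = "curves.tsv"
        counts["curves_total"] = len(curves)
        counts["curves_fitted"] = int(curves["fittable"].sum())
    except Exception as exc:
        raise RuntimeError(f"stage fit failed: {exc}") from exc

    # -- train -------------------------------------------------------------
    try:
        _stage("train")
        pct = _classify.abundance_percentiles(screen.table.mean_vehicle_intensity())
        X, fittable = _classify.build_feature_matrix(curves, pct)
        truth_labels = (screen.truth.set_index(["drug_id", "protein_id"])
                        ["true_label"]
                        .reindex(pd.MultiIndex.from_frame(
                            curves[["drug_id", "protein_id"]]))
                        .to_numpy())
        model, report = _classify.train_classifier(
            X[fittable], truth_labels[fittable],
            split_frac=config.train_frac, seed=seeds["train"],
            n_trees=config.n_trees)
        counts["train_n"] = report.n_train
        counts["validation_n"] = report.n_validation
    except Exception as exc:
        raise RuntimeError(f"stage train failed: {exc}") from exc

    # -- classify + filter -------------------------------------------------
    try:
        _stage("classify")
        labels, prob = _classify.classify_curves(model, X, fittable)
        final = _classify.apply_regulation_filters(
            labels, curves["curve_fold_change"].to_numpy())
        calls = curves[["drug_id", "protein_id", "curve_fold_change",
                        "pec50"]].copy()
        calls["class_label"] = labels
        for i, c in enumerate(_classify.CLASS_ORDER):
            calls[f"prob_{c}"] = prob[:, i]
        calls["final_label"] = final
        write_table(calls, out / "calls.tsv")
        class_paths = write_calls_per_class(calls, out)
        paths["calls"] = "calls.tsv"
        paths.update({f"calls_{k}": p.name for k, p in class_paths.items()})
        for lbl in ("up", "down", "not"):
            counts[f"classified_{lbl}"] = int((labels == lbl).sum())
            counts[f"final_{lbl}"] = int((final == lbl).sum())
    except Exception as exc:
        raise RuntimeError(f"stage classify failed: {exc}") from exc

    # -- enrich ------------------------------------------------------------
    try:
        rng = _stage("enrich")
        planted = _planted_terms(screen, rng) if config.plant_terms else {}
        annotation = generate_annotation(list(screen.table.protein_ids),
                                         config.n_terms, rng, planted=planted)
        write_annotation(annotation, out / "annotation.tsv")
        paths["annotation"] = "annotation.tsv"
        background = set(screen.table.protein_ids)
        cells = []
        for drug in sorted(calls.drug_id.unique()):
            sub = calls[calls.drug_id == drug]
            up = set(sub.loc[sub.final_label == "up", "protein_id"])
            down = set(sub.loc[sub.final_label == "down", "protein_id"])
            combined = _enrich.combine_directions(
                _enrich.enrich_terms(up, annotation, background),
                _enrich.enrich_terms(down, annotation, background))
            combined.insert(0, "drug_id", drug)
            cells.append(combined)
        cells = pd.concat(cells, ignore_index=True)
        paths["enrichment_z"] = "enrichment_z.tsv"
        if cells.empty or cells["drug_id"].nunique() < 2:
            # a screen without regulation calls has nothing to enrich
            write_table(pd.DataFrame(columns=["term_id"]),
                        out / "enrichment_z.tsv")
            counts["terms_enriched"] = 0
            counts["terms_flat"] = 0
        else:
            z, flagged = _enrich.build_matrix(cells)
            write_table(z.rename_axis("term_id").reset_index(),
                        out / "enrichment_z.tsv", sort_by=["term_id"])
            if z.shape[0] >= 2 and z.shape[1] >= 2:
                clust = _enrich.cluster_wpgma(z)
                (out / "terms.nwk").write_text(
                    _enrich.linkage_to_newick(clust.row_linkage, z.index) + "\n")
                (out / "drugs.nwk").write_text(
                    _enrich.linkage_to_newick(clust.col_linkage, z.columns) + "\n")
                paths["term_tree"] = "terms.nwk"
                paths["drug_tree"] = "drugs.nwk"
            counts["terms_enriched"] = int(z.shape[0])
            counts["terms_flat"] = int(flagged.sum())
    except Exception as exc:
        raise RuntimeError(f"stage enrich failed: {exc}") from exc

    # -- qc ----------------------------------------------------------------
    try:
        rng = _stage("qc")
        split = _qc.dmso_split_test(screen.vehicle_pool, seed=seeds["qc"])
        write_table(split.stats, out / "qc_split_test.tsv")
        cov_records, cov_summary = _qc.cov_by_regulation(screen.table, calls)
        write_table(cov_records, out / "qc_cov.tsv")
        drug_table = generate_drug_table(screen, rng)
        n_prot = len(screen.table.protein_ids)
        depths = sorted({max(1, n_prot // 8), n_prot // 4, n_prot // 2, n_prot})
        coverage = _qc.target_coverage_curve(
            screen.table.mean_vehicle_ibaq(), drug_table, depths)
        write_table(coverage.curve.reset_index(), out / "qc_coverage.tsv",
                    sort_by=["depth"])
        paths["qc_split_test"] = "qc_split_test.tsv"
        paths["qc_cov"] = "qc_cov.tsv"
        paths["qc_coverage"] = "qc_coverage.tsv"
        counts["split_test_proteins"] = int(len(split.stats))
        counts["split_test_significant"] = int(
            (split.stats["q"] < 0.05).sum()) if len(split.stats) else 0
    except Exception as exc:
        raise RuntimeError(f"stage qc failed: {exc}") from exc

    manifest = RunManifest(config_hash=config.content_hash(), seed=seed,
                           seeds=seeds, paths=paths, counts=counts)
    manifest.write(out / "manifest.json")
    return manifest
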