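"""Config-driven driver for the two study analyses.

``run_treatment_analysis`` chains normalization -> NB tests for the two
contrasts -> DE calling -> overlap sets -> breadth comparison ->
optional pathway enrichment of the six overlap sets.
``run_signature_analysis`` builds the hypoxia signature from the
hypoxia-vs-untreated table, scores cohort (and optionally cell-line)
samples, compares outcome groups, fits cohort PCA and projects the
cell-line samples.

Both write per-stage TSV tables plus a machine-readable ``report.json``
(schema version ``1.0.0``) and a ``run.log``; every output is
re-derivable from config + inputs + seed alone, and the report embeds a
hash of the config so runs are attributable.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._version import __version__
from .de_sets import call_de, overlap_sets
from .deseq import (
    DE_COLUMNS,
    estimate_dispersions,
    estimate_size_factors,
    nbinom_test,
    normalize,
)
from .enrichment import enrich, enrichment_table
from .errors import ValidationError
from .io import read_cohort, read_count_matrix, read_gmt
from .pca import fit_pca, project_samples
from .signature import build_signature, compare_outcomes, score_samples
from .stats import breadth_comparison

__all__ = ["RunConfig", "run_treatment_analysis", "run_signature_analysis"]

REPORT_SCHEMA_VERSION = "1.0.0"

log = logging.getLogger("hypoxsig.pipeline")


@dataclass
class RunConfig:
    """Paths, contrasts and thresholds for a pipeline run."""

    counts: str | None = None
    sample_sheet: str | None = None
    gmt: str | None = None
    cohort_expr: str | None = None
    cohort_clinical: str | None = None
    contrast_hypoxia: str = "hypoxia:untreated"
    contrast_cocl2: str = "cocl2:untreated"
    padj_max: float = 0.05
    fc_up: float = 2.0
    fc_down: float = 0.5
    signature_padj_max: float = 0.05
    enrich_padj_max: float = 0.05
    score_transform: str = "identity"
    score_mean: bool = False
    pca_transform: str = "log2p1"
    pca_components: int | None = None
    min_gene_overlap: float = 0.5
    seed: int = 0
    outdir: str = "hypoxsig_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def validate_paths(self, required: tuple[str, ...]) -> None:
        for name in required:
            value = getattr(self, name)
            if value is None:
                raise ValidationError(f"config field {name!r} is required")
            if not Path(value).exists():
                raise ValidationError(f"{name}: file not found: {value}")

    def parse_contrast(self, contrast: str) -> tuple[str, str]:
        """``'B:A'`` -> (condition_B, condition_A) (B tested against A)."""
        parts = contrast.split(":")
        if len(parts) != 2 or not all(parts):
            raise ValidationError(f"contrast must be 'B:A', got {contrast!r}")
        return parts[0], parts[1]


def _setup_run(config: RunConfig) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="a")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("hypoxsig")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    log.info("hypoxsig %s, config hash %s", __version__, config.config_hash())
    log.info("thresholds: padj_max=%s fc_up=%s fc_down=%s enrich_padj_max=%s",
             config.padj_max, config.fc_up, config.fc_down,
             config.enrich_padj_max)
    return outdir


def _write_detable(detable, path) -> None:
    detable.loc[:, list(DE_COLUMNS)].to_csv(path, sep="\t", index_label="gene")


def _stage(name):
    """Wrap stage execution so failures carry the stage name."""
    class _ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                log.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return False
    return _ctx()


def _de_for_contrast(cm, sf, disp, config, contrast):
    cond_b, cond_a = config.parse_contrast(contrast)
    declared = set(cm.condition_of.values())
    for c in (cond_a, cond_b):
        if c not in declared:
            raise ValidationError(
                f"contrast condition {c!r} not present in the sample sheet "
                f"(declared: {sorted(declared)})"
            )
    return nbinom_test(cm, sf, disp, cond_a, cond_b)


def run_treatment_analysis(config: RunConfig) -> dict:
    """Treatment comparison: DE in both contrasts, overlap sets, breadth
    test and (when a GMT is configured) enrichment of the six overlap
    sets. Returns the report dict, also written to ``report.json``."""
    config.validate_paths(("counts", "sample_sheet"))
    if config.gmt is not None:
        config.validate_paths(("gmt",))
    # validate contrast syntax before any compute
    config.parse_contrast(config.contrast_hypoxia)
    config.parse_contrast(config.contrast_cocl2)
    outdir = _setup_run(config)

    with _stage("read_counts"):
        cm = read_count_matrix(config.counts, config.sample_sheet)
        for contrast in (config.contrast_hypoxia, config.contrast_cocl2):
            for c in config.parse_contrast(contrast):
                if c not in set(cm.condition_of.values()):
                    raise ValidationError(
                        f"contrast condition {c!r} not in sample sheet"
                    )
    with _stage("size_factors"):
        sf = estimate_size_factors(cm)
        sf.factors.rename_axis("sample").to_csv(outdir / "size_factors.tsv", sep="\t")
    with _stage("dispersions"):
        disp = estimate_dispersions(cm, sf)
        log.info("dispersion curve: a0=%.4g a1=%.4g converged=%s",
                 *disp.fit_coeffs, disp.fit_converged)
    with _stage("de_hypoxia"):
        de_hyp = _de_for_contrast(cm, sf, disp, config, config.contrast_hypoxia)
        _write_detable(de_hyp, outdir / "de_hypoxia.tsv")
    with _stage("de_cocl2"):
        de_co = _de_for_contrast(cm, sf, disp, config, config.contrast_cocl2)
        _write_detable(de_co, outdir / "de_cocl2.tsv")
    with _stage("call_de"):
        hyp_up, hyp_down = call_de(de_hyp, config.padj_max, config.fc_up,
                                   config.fc_down)
        co_up, co_down = call_de(de_co, config.padj_max, config.fc_up,
                                 config.fc_down)
        sets = overlap_sets(hyp_up, hyp_down, co_up, co_down)
        rows = []
        for name in sets.summary_counts():
            for g in sorted(getattr(sets, name)):
                rows.append((g, name))
        with open(outdir / "de_sets.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene\tset\n")
            for g, name in rows:
                fh.write(f"{g}\t{name}\n")
        with open(outdir / "de_set_counts.json", "w", encoding="utf-8") as fh:
            json.dump(sets.summary_counts(), fh, indent=2)
    with _stage("breadth_comparison"):
        breadth, prof_hyp, prof_co = breadth_comparison(de_hyp, de_co)
        np.savetxt(outdir / "abs_l2fc_sorted_hypoxia.tsv", prof_hyp)
        np.savetxt(outdir / "abs_l2fc_sorted_cocl2.tsv", prof_co)

    enrichments = {}
    if config.gmt is not None:
        with _stage("enrichment"):
            collection = read_gmt(config.gmt)
            universe = frozenset(de_hyp.index[de_hyp["flags"] != "untestable"])
            for set_name in ("both_up", "both_down",
                             "hypoxia_only_up", "hypoxia_only_down",
                             "cocl2_only_up", "cocl2_only_down"):
                query = getattr(sets, set_name) & universe
                if not query:
                    log.info("enrichment %s skipped: empty query", set_name)
                    enrichments[set_name] = {"n_query": 0, "n_significant": 0}
                    continue
                results = enrich(query, collection, universe)
                enrichment_table(results).to_csv(
                    outdir / f"enrichment_{set_name}.tsv", sep="\t", index=False
                )
                enrichments[set_name] = {
                    "n_query": len(query),
                    "n_significant": sum(
                        r.padj < config.enrich_padj_max for r in results
                    ),
                    "top": results[0].pathway if results else None,
                }

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "hypoxsig_version": __version__,
        "analysis": "treatment",
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "n_genes": int(cm.counts.shape[0]),
        "n_samples": int(cm.counts.shape[1]),
        "size_factors": {k: float(v) for k, v in sf.factors.items()},
        "dispersion_fit": {
            "a0": disp.fit_coeffs[0],
            "a1": disp.fit_coeffs[1],
            "converged": disp.fit_converged,
            "method": "pooled",
            "sharing_mode": "maximum",
            "fit_type": "parametric",
        },
        "de_set_counts": sets.summary_counts(),
        "breadth": {
            "statistic": breadth.statistic,
            "p_value": breadth.p_value,
            "p_display": breadth.format_p(),
            "method": breadth.method,
            "n_genes_compared": breadth.n1,
        },
        "enrichment": enrichments,
    }
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def run_signature_analysis(config: RunConfig) -> dict:
    """Signature validation: build the hypoxia signature, score cohort
    and cell-line samples, compare outcome groups and project the
    cell-line samples onto cohort principal components."""
    config.validate_paths(("counts", "sample_sheet", "cohort_expr",
                           "cohort_clinical"))
    outdir = _setup_run(config)

    with _stage("de_hypoxia"):
        cm = read_count_matrix(config.counts, config.sample_sheet)
        sf = estimate_size_factors(cm)
        disp = estimate_dispersions(cm, sf)
        de_hyp = _de_for_contrast(cm, sf, disp, config, config.contrast_hypoxia)
        _write_detable(de_hyp, outdir / "de_hypoxia.tsv")
    with _stage("build_signature"):
        signature = build_signature(de_hyp, config.signature_padj_max,
                                    contrast=config.contrast_hypoxia)
        signature.weights.rename("weight").rename_axis("gene").to_csv(
            outdir / "signature.tsv", sep="\t"
        )
        log.info("signature: %d genes", len(signature))
    with _stage("read_cohort"):
        cohort, clinical = read_cohort(config.cohort_expr, config.cohort_clinical)
    with _stage("score_cohort"):
        cohort_report = score_samples(signature, cohort,
                                      transform=config.score_transform,
                                      mean=config.score_mean)
        cohort_scores = cohort_report.scores.rename("score").rename_axis("sample")
        cohort_scores.to_frame().assign(
            n_used=cohort_report.n_genes_used,
            n_missing=cohort_report.n_genes_missing,
        ).to_csv(outdir / "cohort_scores.tsv", sep="\t")
    with _stage("score_celllines"):
        cellline_expr = normalize(cm, sf)
        cellline_report = score_samples(signature, cellline_expr,
                                        transform=config.score_transform,
                                        mean=config.score_mean)
        cellline_report.scores.rename("score").rename_axis("sample").to_csv(
            outdir / "cellline_scores.tsv", sep="\t"
        )

    outcome = None
    try:
        with _stage("compare_outcomes"):
            outcome = compare_outcomes(cohort_report, clinical)
    except RuntimeError as exc:
        if isinstance(exc.__cause__, ValidationError):
            log.warning("outcome comparison skipped: %s", exc.__cause__)
        else:
            raise

    with _stage("fit_pca"):
        model, cohort_coords = fit_pca(cohort, transform=config.pca_transform,
                                       n_components=config.pca_components)
        cohort_coords.rename_axis("sample").to_csv(
            outdir / "cohort_pca_coordinates.tsv", sep="\t"
        )
    with _stage("project_samples"):
        cell_coords = project_samples(model, cellline_expr,
                                      min_gene_overlap=config.min_gene_overlap)
        cell_coords.rename_axis("sample").to_csv(
            outdir / "cellline_pca_coordinates.tsv", sep="\t"
        )

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "hypoxsig_version": __version__,
        "analysis": "signature",
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "signature": {
            "n_genes": len(signature),
            "padj_max": config.signature_padj_max,
            "contrast": config.contrast_hypoxia,
        },
        "cohort_scoring": {
            "n_samples": int(len(cohort_report.scores)),
            "n_genes_used": cohort_report.n_genes_used,
            "n_genes_missing": cohort_report.n_genes_missing,
            "transform": cohort_report.transform,
        },
        "outcome_comparison": None if outcome is None else {
            "n_recurred_progressed": outcome["n_recurred_progressed"],
            "n_disease_free": outcome["n_disease_free"],
            "median_recurred_progressed": outcome["median_recurred_progressed"],
            "median_disease_free": outcome["median_disease_free"],
            "p_value": outcome["test"].p_value,
            "p_display": outcome["test"].format_p(),
            "method": outcome["test"].method,
        },
        "pca": {
            "n_components": model.n_components,
            "explained_variance_ratio": [
                float(v) for v in model.explained_variance_ratio
            ],
            "transform": model.transform,
        },
    }
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
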