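"""End-to-end orchestration: simulate/load -> RFI -> preprocess -> rank -> CV.

A run is described by one :class:`RunConfig` (YAML/JSON-loadable) holding
either input paths (counts TSV + phenotype CSV) or a :class:`SimConfig`, and
produces a directory of artifacts: phenotype table with RFI, adjusted
expression matrix, gene ranking, learner comparison table, gene-importance
report and a manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rficlass._seeds import stage_seed
from rficlass.crossval import (
    ResamplingPlan,
    aggregate_gene_importance,
    compare_learners,
)
from rficlass.errors import ConfigurationError, ValidationError
from rficlass.learners import DEFAULT_LEARNERS
from rficlass.preprocess import (
    adjust_for_components,
    batch_association,
    normalize,
    run_pca,
    top_variable_genes,
)
from rficlass.ranking import ForestConfig, build_forest, conditional_importance
from rficlass.rfi import contrast_classes, fit_rfi
from rficlass.simulate import CountMatrix, SimConfig, generate_counts, generate_phenotypes

ARTIFACTS = (
    "phenotypes_rfi.csv",
    "adjusted_matrix.tsv",
    "ranking.csv",
    "comparison.csv",
    "importance.csv",
    "manifest.json",
)


@dataclass
class RunConfig:
    counts_tsv: str | None = None
    phenotypes_csv: str | None = None
    sim: SimConfig | None = None
    adjust_components: tuple[int, ...] = (1,)
    n_top_variable: int = 500
    filter_min_total: int = 10
    subset_sizes: tuple[int, ...] = (50, 75, 100, 125)
    learners: tuple[str, ...] = ("ENET", "SVM", "RF", "PAM")
    plan: ResamplingPlan = field(default_factory=ResamplingPlan)
    forest: ForestConfig = field(default_factory=ForestConfig)
    out_dir: str = "results/run"
    seed: int = 0
    # 'outer' re-ranks genes inside each outer-training set (leakage-safe
    # default); 'global' ranks once on the full cohort, matching the original
    # two-step description of the procedure
    rank_scope: str = "outer"

    def __post_init__(self) -> None:
        has_paths = self.counts_tsv is not None or self.phenotypes_csv is not None
        if has_paths and self.sim is not None:
            raise ConfigurationError("give input paths or a SimConfig, not both")
        if not has_paths and self.sim is None:
            raise ConfigurationError("give input paths or a SimConfig")
        if has_paths and (self.counts_tsv is None or self.phenotypes_csv is None):
            raise ConfigurationError("both counts_tsv and phenotypes_csv are required")
        unknown = set(self.learners) - set(DEFAULT_LEARNERS)
        if unknown:
            raise ConfigurationError(f"unknown learners: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "sim" in raw and raw["sim"] is not None:
            sim = raw.pop("sim")
            if "class_balance" in sim:
                sim["class_balance"] = tuple(sim["class_balance"])
            if "pheno_betas" in sim:
                sim["pheno_betas"] = tuple(sim["pheno_betas"])
            raw["sim"] = SimConfig(**sim)
        if "plan" in raw and raw["plan"] is not None:
            raw["plan"] = ResamplingPlan(**raw.pop("plan"))
        if "forest" in raw and raw["forest"] is not None:
            raw["forest"] = ForestConfig(**raw.pop("forest"))
        for key in ("adjust_components", "subset_sizes", "learners"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def validate_inputs(counts_tsv, phenotypes_csv) -> dict:
    """Schema checks on input files; returns a machine-readable report."""
    issues = []
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    pheno = pd.read_csv(phenotypes_csv)
    id_col = "animal_id" if "animal_id" in pheno.columns else "sample_id"
    if id_col not in pheno.columns:
        issues.append("phenotype table lacks an animal_id/sample_id column")
        return {"ok": False, "issues": issues}

    neg = np.argwhere(counts.to_numpy() < 0)
    for g, s in neg[:20]:
        issues.append(
            f"negative count at gene {counts.index[g]}, sample {counts.columns[s]}"
        )
    vals = counts.to_numpy()
    if not np.allclose(vals, np.round(vals)):
        issues.append("counts contain non-integer values")
    if counts.index.duplicated().any():
        dups = list(counts.index[counts.index.duplicated()][:10])
        issues.append(f"duplicated gene ids: {dups}")
    if pheno[id_col].duplicated().any():
        dups = list(pheno[id_col][pheno[id_col].duplicated()][:10])
        issues.append(f"duplicated animal ids: {dups}")

    count_ids = set(counts.columns)
    pheno_ids = set(pheno[id_col])
    missing = sorted(count_ids - pheno_ids)
    if missing:
        issues.append(f"count-matrix samples missing from phenotypes: {missing}")
    extra = sorted(pheno_ids - count_ids)
    if extra:
        issues.append(f"phenotype animals missing from count matrix: {extra}")

    for col, levels in (("sex", {"female", "male"}),
                        ("rfi_class", {"high", "low", "mid", "unselected"})):
        if col in pheno.columns:
            bad = set(pheno[col].dropna().astype(str)) - levels
            if bad:
                issues.append(f"unexpected {col} levels: {sorted(bad)}")
    needed = [c for c in ("FI", "MBW", "ADG", "BFG") if c not in pheno.columns]
    if needed:
        issues.append(f"phenotype table lacks covariates: {needed}")
    return {"ok": len(issues) == 0, "issues": issues}


def _load_inputs(cfg: RunConfig) -> tuple[CountMatrix, pd.DataFrame]:
    if cfg.sim is not None:
        cm = generate_counts(cfg.sim)
        pheno = generate_phenotypes(cfg.sim, cm.meta["rfi_class"].to_numpy())
        return cm, pheno
    report = validate_inputs(cfg.counts_tsv, cfg.phenotypes_csv)
    if not report["ok"]:
        raise ValidationError("; ".join(report["issues"]))
    pheno = pd.read_csv(cfg.phenotypes_csv)
    id_col = "animal_id" if "animal_id" in pheno.columns else "sample_id"
    meta_cols = [c for c in (id_col, "rfi_class", "sex", "protocol") if c in pheno]
    meta = pheno[meta_cols].rename(columns={id_col: "sample_id"})
    counts = pd.read_csv(cfg.counts_tsv, sep="\t", index_col=0)
    counts = counts[meta["sample_id"]]
    return CountMatrix(counts=counts, meta=meta), pheno


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage and write the artifact directory; returns its path."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        cm, pheno = _load_inputs(cfg)

        model = fit_rfi(pheno)
        pheno_rfi = model.table
        path = out / "phenotypes_rfi.csv"
        pheno_rfi.to_csv(path, index=False)
        written.append(path)
        contrast = contrast_classes(pheno_rfi)

        em = normalize(cm, filter_min_total=cfg.filter_min_total)
        hv = top_variable_genes(em, k=min(cfg.n_top_variable, em.shape[0]))
        pca = run_pca(em, hv)
        covs = cm.meta.set_index("sample_id")[["sex", "protocol", "rfi_class"]]
        assoc = batch_association(pca, covs, n_components=5)
        adj = adjust_for_components(em, pca, which=cfg.adjust_components)
        path = out / "adjusted_matrix.tsv"
        adj.values.to_csv(path, sep="\t", index_label="gene_id")
        written.append(path)

        y = cm.meta["rfi_class"].to_numpy()
        fcfg = dataclasses.replace(cfg.forest, seed=stage_seed(cfg.seed, "forest"))
        forest = build_forest(adj.values, y, fcfg)
        ranking = conditional_importance(forest, adj.values, y)
        path = out / "ranking.csv"
        ranking.to_csv(path, index=False)
        written.append(path)

        plan = dataclasses.replace(cfg.plan, seed=stage_seed(cfg.seed, "folds"))
        learners = {name: DEFAULT_LEARNERS[name]() for name in cfg.learners}
        scope = "global" if cfg.rank_scope == "global" else "outer"
        long_df, summary, reports = compare_learners(
            adj.values, y, learners, cfg.subset_sizes, plan, ranking=ranking,
            rank_scope=scope, forest_cfg=fcfg,
        )
        path = out / "comparison.csv"
        long_df.to_csv(path, index=False)
        written.append(path)
        summary.to_csv(out / "comparison_summary.csv", index=False)

        importance = aggregate_gene_importance(
            [r for r in reports if r.has_selection]
        )
        path = out / "importance.csv"
        importance.to_csv(path, index=False)
        written.append(path)

        manifest = {
            "seed": cfg.seed,
            "n_samples": int(cm.counts.shape[1]),
            "n_genes": int(cm.counts.shape[0]),
            "adjust_components": list(cfg.adjust_components),
            "subset_sizes": list(cfg.subset_sizes),
            "learners": list(cfg.learners),
            "plan": dataclasses.asdict(plan),
            "max_votes": plan.repetitions * plan.outer_folds * plan.inner_folds,
            "pc_var_explained": [float(v) for v in pca.var_explained[:5]],
            "flagged_components": assoc[assoc["flagged"]][
                ["component", "covariate"]
            ].to_dict(orient="records"),
            "rfi_contrast": contrast.to_json_dict(),
            "forest_mtry": forest.mtry,
        }
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2))
        written.append(path)
        return out
    except Exception:
        for p in written:  # no partial artifact directories
            p.unlink(missing_ok=True)
        raise
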