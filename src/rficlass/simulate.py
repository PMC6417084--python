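"""Synthetic cohorts with the structure the downstream analysis assumes.

The generator emulates a feed-efficiency trial: ~65 animals split into two
slightly unbalanced residual-feed-intake (RFI) classes, negative-binomial
RNA-Seq counts with variable library sizes, a small set of class-associated
genes shifted on the log2 scale, and a single latent batch axis — correlated
with sex — loading on half of the genes so that the leading principal
component of the log-normalized matrix captures a configurable variance
fraction.  Phenotypes follow the RFI model: feed intake is a within-sex linear
function of metabolic body weight, daily gain and backfat gain plus a
class-linked residual component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rficlass._seeds import stage_rng
from rficlass.errors import ConfigurationError

_LN2_SQ = np.log(2.0) ** 2


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror the trial the pipeline was designed around: 65 animals in
    a 32/33 class split, ~12,560 genes, a batch axis explaining ~30% of
    log-expression variance and strongly correlated with sex, and a
    class effect on feed intake of 0.45 kg/day (between the two printed
    sex-specific class gaps of 0.56 and 0.31 kg/day).
    """

    n_samples: int = 65
    n_genes: int = 12560
    n_signal_genes: int = 50
    signal_logfc: float = 1.5  # log2 units, high vs low class
    batch_variance_frac: float = 0.3
    sex_batch_corr: float = 0.9
    dispersion: float = 0.1
    mean_lib_size: int = 1_000_000
    class_balance: tuple[int, int] = (32, 33)  # (high, low)
    pheno_betas: tuple[float, float, float] = (0.08, 0.7, 0.01)  # MBW, ADG, BFG
    pheno_noise_sd: float = 0.15  # kg/day
    class_effect_on_fi: float = 0.45  # kg/day, high minus low
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_signal_genes", "mean_lib_size", "seed"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ConfigurationError(f"{name} must be an integer, got {v!r}")
        if self.n_samples < 2 or self.n_genes < 1 or self.mean_lib_size < 1:
            raise ConfigurationError("n_samples, n_genes, mean_lib_size must be positive")
        if self.n_signal_genes < 0 or self.n_signal_genes > self.n_genes:
            raise ConfigurationError("need 0 <= n_signal_genes <= n_genes")
        if not 0.0 <= self.batch_variance_frac < 1.0:
            raise ConfigurationError("batch_variance_frac must lie in [0, 1)")
        if not -1.0 <= self.sex_batch_corr <= 1.0:
            raise ConfigurationError("sex_batch_corr must lie in [-1, 1]")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        n_high, n_low = self.class_balance
        if (
            not all(isinstance(v, (int, np.integer)) for v in (n_high, n_low))
            or n_high < 0
            or n_low < 0
        ):
            raise ConfigurationError("class_balance must be non-negative integers")
        if n_high + n_low != self.n_samples:
            raise ConfigurationError(
                f"class sizes {self.class_balance} must sum to n_samples={self.n_samples}"
            )
        if self.pheno_noise_sd < 0:
            raise ConfigurationError("pheno_noise_sd must be >= 0")


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus the sample metadata used downstream."""

    counts: pd.DataFrame  # genes in rows, samples in columns
    meta: pd.DataFrame  # sample_id, rfi_class, sex, protocol
    signal_genes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, meta: pd.DataFrame | None = None) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        if meta is None:
            meta = pd.DataFrame({"sample_id": counts.columns})
        return cls(counts=counts, meta=meta)


def cohort_design(cfg: SimConfig) -> pd.DataFrame:
    """Deterministic design table: sample ids, class labels, sex, protocol.

    Sexes are balanced within class (the extra animal of the larger class is
    male, matching the 16/16/17/16 layout of the motivating trial) and the
    four feeding protocols cycle within each sex-by-class cell.
    """
    n_high, n_low = cfg.class_balance
    rows = []
    for label, n in (("high", n_high), ("low", n_low)):
        for i in range(n):
            sex = "female" if i % 2 == 0 else "male"
            rows.append((label, sex))
    # protocol cycles within sex x class so cells stay near-balanced
    df = pd.DataFrame(rows, columns=["rfi_class", "sex"])
    df["sample_id"] = [f"A{i + 1:03d}" for i in range(len(df))]
    df["protocol"] = ""
    for (_, _), idx in df.groupby(["rfi_class", "sex"]).groups.items():
        df.loc[idx, "protocol"] = [f"T{(j % 4) + 1}" for j in range(len(idx))]
    return df[["sample_id", "rfi_class", "sex", "protocol"]]


def _batch_factor(cfg: SimConfig, sex: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Latent continuous batch variable with corr(batch, sex) ~ sex_batch_corr."""
    sex01 = (sex == "male").astype(float)
    s = sex01 - sex01.mean()
    sd = s.std()
    s = s / sd if sd > 0 else s
    z = rng.standard_normal(len(sex01))
    z = (z - z.mean()) / z.std()
    # remove the empirical sex component of z so the realized correlation is exact
    z = z - (z @ s) / len(z) * s
    z_sd = z.std()
    z = z / z_sd if z_sd > 0 else z
    rho = cfg.sex_batch_corr
    return rho * s + np.sqrt(max(0.0, 1.0 - rho**2)) * z


def generate_counts(cfg: SimConfig) -> CountMatrix:
    """Draw a negative-binomial count matrix with planted class and batch axes.

    Gene baseline abundances are log-normal; the class effect shifts signal
    genes by ``signal_logfc`` log2 units between classes; the batch axis adds
    ``lambda * b_s`` to a random half of the genes, with the common loading
    ``lambda`` set analytically so the batch variance is the requested
    fraction of total log-scale variance.  Counts are Gamma-Poisson
    (negative binomial) with a single dispersion and per-sample library-size
    multipliers.
    """
    design = cohort_design(cfg)
    rng = stage_rng(cfg.seed, "counts")
    G, S = cfg.n_genes, cfg.n_samples

    base_log2 = rng.normal(loc=3.0, scale=1.8, size=G)
    w = 2.0**base_log2
    rel = w / w.sum()
    mu_bar = cfg.mean_lib_size * rel  # typical per-gene count

    gene_ids = pd.Index([f"G{i + 1:05d}" for i in range(G)], name="gene_id")
    signal_idx = rng.choice(G, size=cfg.n_signal_genes, replace=False)
    signal_sign = rng.choice([-1.0, 1.0], size=cfg.n_signal_genes)

    batch_idx = rng.choice(G, size=G // 2, replace=False)
    batch_sign = rng.choice([-1.0, 1.0], size=len(batch_idx))

    # analytic log2-scale noise variance of log2(count + 0.5) by delta method,
    # used to calibrate the common batch loading
    var_noise = mu_bar * (1.0 + cfg.dispersion * mu_bar) / ((mu_bar + 0.5) ** 2 * _LN2_SQ)
    total_noise = float(var_noise.sum())
    f = cfg.batch_variance_frac
    if f > 0 and len(batch_idx) > 0:
        lam = np.sqrt(f / (1.0 - f) * total_noise / len(batch_idx))
    else:
        lam = 0.0

    b = _batch_factor(cfg, design["sex"].to_numpy(), rng)
    cls = (design["rfi_class"] == "high").to_numpy().astype(float)  # 1 = high
    cls_centered = cls - 0.5  # +/- half the logFC per class

    delta = np.zeros((G, S))
    delta[signal_idx, :] += (
        signal_sign[:, None] * cfg.signal_logfc * cls_centered[None, :]
    )
    delta[batch_idx, :] += lam * batch_sign[:, None] * b[None, :]

    sigma_lib = 0.2
    lib = cfg.mean_lib_size * rng.lognormal(-(sigma_lib**2) / 2, sigma_lib, size=S)

    q = w[:, None] * 2.0**delta
    p = q / q.sum(axis=0, keepdims=True)
    mu = lib[None, :] * p

    shape = 1.0 / cfg.dispersion
    lam_nb = rng.gamma(shape=shape, scale=mu * cfg.dispersion)
    counts = rng.poisson(lam_nb).astype(np.int64)

    df = pd.DataFrame(counts, index=gene_ids, columns=design["sample_id"].to_numpy())
    return CountMatrix(
        counts=df,
        meta=design,
        signal_genes=list(gene_ids[np.sort(signal_idx)]),
    )


# phenotype distribution defaults: body weight ~ N(105, 7) kg at end of test
# (metabolic body weight = BW^0.75), average daily gain ~ N(0.95, 0.07) kg/day,
# backfat gain over the trial ~ N(6, 1.5) mm; sex intercepts on feed intake in
# kg/day.  These are documented choices for a realistic grower-finisher cohort.
_SEX_INTERCEPTS = {"female": -0.85, "male": -1.0}
_BW_MEAN, _BW_SD = 105.0, 7.0
_ADG_MEAN, _ADG_SD = 0.95, 0.07
_BFG_MEAN, _BFG_SD = 6.0, 1.5


def generate_phenotypes(cfg: SimConfig, class_labels) -> pd.DataFrame:
    """Phenotype table whose feed intake follows the within-sex RFI model.

    FI = S_sex + beta_MBW*MBW + beta_ADG*ADG + beta_BFG*BFG
         + class_effect_on_fi * (class indicator, centered) + N(0, noise_sd).

    ``class_labels`` must align with the cohort design (length n_samples,
    values 'high'/'low').
    """
    labels = np.asarray(class_labels, dtype=object)
    if len(labels) != cfg.n_samples:
        raise ConfigurationError(
            f"class_labels has length {len(labels)}, expected {cfg.n_samples}"
        )
    design = cohort_design(cfg)
    rng = stage_rng(cfg.seed, "phenotypes")

    bw = rng.normal(_BW_MEAN, _BW_SD, size=cfg.n_samples)
    mbw = bw**0.75
    adg = rng.normal(_ADG_MEAN, _ADG_SD, size=cfg.n_samples)
    bfg = rng.normal(_BFG_MEAN, _BFG_SD, size=cfg.n_samples)

    b_mbw, b_adg, b_bfg = cfg.pheno_betas
    intercept = design["sex"].map(_SEX_INTERCEPTS).to_numpy()
    ind = (labels == "high").astype(float)
    fi = (
        intercept
        + b_mbw * mbw
        + b_adg * adg
        + b_bfg * bfg
        + cfg.class_effect_on_fi * (ind - ind.mean())
        + rng.normal(0.0, cfg.pheno_noise_sd, size=cfg.n_samples)
    )

    table = design.rename(columns={"sample_id": "animal_id"})
    table["rfi_class"] = labels
    table["FI"] = fi
    table["MBW"] = mbw
    table["ADG"] = adg
    table["BFG"] = bfg
    table["RFI"] = np.nan
    return table


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)
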