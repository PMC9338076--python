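"""Per-tissue eQTL association testing of spatially confirmed pairs.

The model is the standard single-variant eQTL regression: for each
spatially confirmed (variant, gene) pair and each tissue,

    y_transformed = alpha + beta * dosage + epsilon

where ``y_transformed`` is the rank-based inverse-normal transform of the
gene's expression in that tissue (per gene, per tissue) and ``dosage`` is
the alternate-allele count in {0, 1, 2}.  Two-sided p-values come from the
t distribution with n - 2 degrees of freedom.  Variants with cohort minor
allele frequency below ``maf_min`` (default 5%) are removed before testing,
and Benjamini-Hochberg adjustment is applied once across all tests of the
run; associations with adjusted p < alpha are declared spatial
eQTL-eGene pairs.

Exposed statsmodels-style: build a :class:`SpatialEQTL` model from the
spatial-pair table, the dosage matrix and the per-tissue expression
matrices, then ``fit()`` to obtain a :class:`SpatialEQTLResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "compute_maf",
    "inverse_normal_transform",
    "test_association",
    "bh_adjust",
    "SpatialEQTL",
    "SpatialEQTLResults",
    "run_spatial_eqtl",
    "export_manhattan",
    "ConstantExpressionError",
    "MonomorphicError",
    "DegenerateFitError",
]

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8     # red reference line on the Manhattan export
SUGGESTIVE_P = 1e-5      # blue reference line


class ConstantExpressionError(ValueError):
    """Expression vector is constant; the gene is untestable in this tissue."""


class MonomorphicError(ValueError):
    """Dosage has zero variance in the analysed samples."""


class DegenerateFitError(ValueError):
    """Residual variance is (numerically) zero; the t statistic is undefined."""


def compute_maf(dosages: np.ndarray | pd.Series) -> float:
    """Minor allele frequency from dosages in {0, 1, 2}: min(f, 1 - f)."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("cannot compute MAF of an empty dosage vector")
    f = d.sum() / (2 * d.size)
    return float(min(f, 1.0 - f))


def inverse_normal_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse-normal transform: Phi^-1((rank - 0.5) / n).

    Ties are broken by stable input order, so the transform is a strictly
    monotone relabelling of the input and equivariant under permutation.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("inverse-normal transform needs at least 3 values")
    if np.ptp(x) == 0:
        raise ConstantExpressionError("constant expression vector is untestable")
    ranks = stats.rankdata(x, method="ordinal")
    return stats.norm.ppf((ranks - 0.5) / x.size)


def test_association(
    dosages: np.ndarray | pd.Series, expression: np.ndarray | pd.Series
) -> tuple[float, float, float]:
    """OLS of (transformed) expression on dosage with intercept.

    Returns (beta, se, p) with the two-sided p from t(n - 2).
    """
    g = np.asarray(dosages, dtype=float)
    y = np.asarray(expression, dtype=float)
    if g.shape != y.shape:
        raise ValueError("dosage and expression vectors differ in length")
    if g.size < 10:
        raise ValueError(f"need >= 10 samples, got {g.size}")
    if np.ptp(g) == 0:
        raise MonomorphicError("dosage is constant in the analysed samples")
    res = stats.linregress(g, y)
    if not np.isfinite(res.stderr) or res.stderr == 0:
        raise DegenerateFitError("zero residual variance: perfect fit, se undefined")
    return float(res.slope), float(res.stderr), float(res.pvalue)


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------- model


class SpatialEQTL:
    """Spatial eQTL association model.

    Parameters
    ----------
    pairs
        SpatialPair table (``rsid, gene_id, category, distance, ...``)
        from :func:`spatialeqtl.spatial.map_spatial_pairs`.
    dosages
        samples x variants dosage matrix (values 0/1/2, NaN for missing).
    expression
        mapping tissue id -> samples x genes expression matrix.
    maf_min
        cohort MAF threshold; variants below it are removed before testing.
    transform
        "inverse_normal" (default) rank-normalises expression per gene and
        tissue before the regression; "raw" uses expression as given.
    covariates
        optional samples x covariates matrix; expression is residualised on
        it (with intercept) before the transform.
    """

    def __init__(
        self,
        pairs: pd.DataFrame,
        dosages: pd.DataFrame,
        expression: Mapping[str, pd.DataFrame],
        *,
        maf_min: float = 0.05,
        transform: Literal["inverse_normal", "raw"] = "inverse_normal",
        covariates: pd.DataFrame | None = None,
    ):
        if not 0 <= maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        if transform not in ("inverse_normal", "raw"):
            raise ValueError(f"unknown transform {transform!r}")
        missing = set(pairs["rsid"]) - set(dosages.columns)
        if missing:
            raise KeyError(f"pairs reference variants absent from dosages: {sorted(missing)[:5]}")
        self.pairs = pairs.reset_index(drop=True)
        self.dosages = dosages
        self.expression = dict(expression)
        self.maf_min = maf_min
        self.transform = transform
        self.covariates = covariates

    @classmethod
    def from_files(
        cls,
        pairs_path: str | Path,
        vcf_path: str | Path,
        expression_dir: str | Path,
        **kwargs,
    ) -> "SpatialEQTL":
        from . import io

        pairs = pd.read_csv(pairs_path, sep="\t")
        _, dosages = io.read_vcf(vcf_path)
        expression = io.read_expression(expression_dir)
        return cls(pairs, dosages, expression, **kwargs)

    # -- internals --

    def _transformed_column(self, tissue: str, gene_id: str, samples: pd.Index) -> pd.Series | None:
        mat = self.expression[tissue]
        if gene_id not in mat.columns:
            return None
        y = mat.loc[samples, gene_id]
        if self.covariates is not None:
            X = np.column_stack(
                [np.ones(len(samples)), self.covariates.loc[samples].to_numpy(dtype=float)]
            )
            beta, *_ = np.linalg.lstsq(X, y.to_numpy(dtype=float), rcond=None)
            y = pd.Series(y.to_numpy(dtype=float) - X @ beta, index=samples)
        if self.transform == "inverse_normal":
            return pd.Series(inverse_normal_transform(y), index=samples)
        return y

    def fit(
        self,
        alpha: float = 0.05,
        bh_family: Literal["pooled", "per_tissue"] = "pooled",
    ) -> "SpatialEQTLResults":
        """Run every surviving (pair x tissue) test and adjust with BH.

        ``bh_family="pooled"`` (default) forms one BH family across all
        tissues and pairs of the run.
        """
        maf = {rsid: compute_maf(self.dosages[rsid]) for rsid in self.pairs["rsid"].unique()}
        kept = self.pairs[self.pairs["rsid"].map(maf) >= self.maf_min]
        n_maf_filtered = self.pairs["rsid"].nunique() - kept["rsid"].nunique()

        rows = []
        skipped: list[dict] = []
        transformed_cache: dict[tuple[str, str], pd.Series | None] = {}
        for tissue in sorted(self.expression):
            expr_samples = self.expression[tissue].index
            samples = self.dosages.index.intersection(expr_samples)
            for pair in kept.itertuples(index=False):
                key = (tissue, pair.gene_id)
                try:
                    if key not in transformed_cache:
                        transformed_cache[key] = self._transformed_column(
                            tissue, pair.gene_id, samples
                        )
                    y = transformed_cache[key]
                    if y is None:
                        raise KeyError(f"gene {pair.gene_id} missing from tissue {tissue}")
                    g = self.dosages.loc[samples, pair.rsid]
                    ok = g.notna() & y.notna()
                    beta, se, p = test_association(g[ok], y[ok])
                except (KeyError, ValueError) as exc:
                    skipped.append(
                        {"rsid": pair.rsid, "gene_id": pair.gene_id,
                         "tissue_id": tissue, "reason": str(exc)}
                    )
                    logger.warning("skipped %s/%s/%s: %s", pair.rsid, pair.gene_id, tissue, exc)
                    continue
                rows.append(
                    (pair.rsid, pair.gene_id, tissue, int(ok.sum()), maf[pair.rsid],
                     beta, se, p, pair.category, pair.distance)
                )

        table = pd.DataFrame(
            rows,
            columns=["rsid", "gene_id", "tissue_id", "n_samples", "maf",
                     "beta", "se", "p", "category", "distance"],
        )
        if len(table):
            if bh_family == "pooled":
                table["p_adj"] = bh_adjust(table["p"])
            else:
                table["p_adj"] = np.nan
                for tissue, idx in table.groupby("tissue_id").groups.items():
                    table.loc[idx, "p_adj"] = bh_adjust(table.loc[idx, "p"])
            table["significant"] = table["p_adj"] < alpha
            table = table.sort_values(["p", "rsid", "gene_id", "tissue_id"]).reset_index(drop=True)
        else:
            table["p_adj"] = pd.Series(dtype=float)
            table["significant"] = pd.Series(dtype=bool)
        return SpatialEQTLResults(
            model=self,
            table=table,
            alpha=alpha,
            bh_family=bh_family,
            skipped=pd.DataFrame(skipped, columns=["rsid", "gene_id", "tissue_id", "reason"]),
            n_maf_filtered=n_maf_filtered,
        )


@dataclass
class SpatialEQTLResults:
    """Fitted spatial eQTL associations.

    ``table`` has one row per tested (variant, gene, tissue): effect size
    ``beta`` (transformed-expression units per alternate allele), its
    standard error, two-sided ``p``, BH-adjusted ``p_adj``, the
    ``significant`` flag (p_adj < alpha, strict) and the spatial category.
    """

    model: SpatialEQTL
    table: pd.DataFrame
    alpha: float
    bh_family: str
    skipped: pd.DataFrame
    n_maf_filtered: int
    variants: pd.DataFrame | None = field(default=None)

    @property
    def n_tests(self) -> int:
        return len(self.table)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    @property
    def significant_variants(self) -> list[str]:
        return sorted(self.significant["rsid"].unique())

    def category_counts(self, significant_only: bool = True) -> pd.Series:
        """Distinct (variant, gene) pairs per spatial category."""
        t = self.significant if significant_only else self.table
        return (
            t.drop_duplicates(["rsid", "gene_id"])["category"]
            .value_counts()
            .reindex(["cis", "trans_intra", "trans_inter"], fill_value=0)
        )

    def summary(self) -> str:
        sig = self.significant
        cats = self.category_counts()
        lines = [
            "Spatial eQTL results",
            "=" * 48,
            f"tests run            {self.n_tests}",
            f"tests skipped        {self.n_skipped}",
            f"variants MAF-filtered {self.n_maf_filtered}",
            f"BH family            {self.bh_family}",
            f"alpha (adjusted p)    {self.alpha}",
            f"significant tests     {len(sig)}",
            f"significant variants  {sig['rsid'].nunique()}",
            f"significant genes     {sig['gene_id'].nunique()}",
            f"pairs by category     cis={cats['cis']} trans_intra={cats['trans_intra']} "
            f"trans_inter={cats['trans_inter']}",
        ]
        if len(sig):
            lines += ["", "top associations:",
                      sig.head(10).to_string(index=False, float_format=lambda v: f"{v:.3g}")]
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def manhattan(self, variants: pd.DataFrame | None = None) -> pd.DataFrame:
        variants = variants if variants is not None else self.variants
        return export_manhattan(self.table, variants)


def run_spatial_eqtl(
    spatial_pairs: pd.DataFrame,
    genotypes: pd.DataFrame,
    expression_by_tissue: Mapping[str, pd.DataFrame],
    maf_min: float = 0.05,
    alpha: float = 0.05,
    **model_kwargs,
) -> SpatialEQTLResults:
    """Functional wrapper: build the model and fit in one call."""
    model = SpatialEQTL(
        spatial_pairs, genotypes, expression_by_tissue, maf_min=maf_min, **model_kwargs
    )
    return model.fit(alpha=alpha)


def export_manhattan(
    results: pd.DataFrame, variants: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-variant minimum p across tissues with genome-wide reference flags.

    Columns flag the conventional GWAS reference thresholds p < 5e-8
    ("red line") and p < 1e-5 ("blue line").
    """
    cols = ["rsid", "chromosome", "position", "p_min",
            "below_red_line_5e-8", "below_blue_line_1e-5"]
    if len(results) == 0:
        return pd.DataFrame(columns=cols)
    pmin = results.groupby("rsid", sort=True)["p"].min().rename("p_min").reset_index()
    if variants is not None:
        pmin = pmin.merge(
            variants[["rsid", "chromosome", "position"]], on="rsid", how="left"
        )
    else:
        pmin["chromosome"] = pd.NA
        pmin["position"] = pd.NA
    pmin["below_red_line_5e-8"] = pmin["p_min"] < GENOME_WIDE_P
    pmin["below_blue_line_1e-5"] = pmin["p_min"] < SUGGESTIVE_P
    return pmin[cols]
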