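"""Downstream validation: embedding plots, trait correlation, association scan.

The association scan is a deliberately simple per-marker ordinary
least-squares regression with a Bonferroni family-wise threshold. The
synthetic genotype panel has independent loci by construction, so no
kinship/mixed-model correction is applied (or needed) here; real panels with
population structure should go through a dedicated GWAS tool instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .datamodel import GenotypeMatrix

__all__ = [
    "AssociationResult",
    "embedding_plot",
    "trait_phenotype_correlation",
    "association_scan",
    "manhattan_plot",
]


@dataclass
class AssociationResult:
    snp_ids: list
    beta: np.ndarray
    stat: np.ndarray
    p: np.ndarray
    alpha: float
    bonferroni_threshold: float
    significant_indices: np.ndarray
    causal_index: Optional[int] = None
    false_positive_count: Optional[int] = None

    def to_frame(self) -> pd.DataFrame:
        sig = np.zeros(len(self.snp_ids), dtype=bool)
        sig[self.significant_indices] = True
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "beta": self.beta, "stat": self.stat, "p": self.p, "significant": sig}
        )


def trait_phenotype_correlation(traits, phenotypes):
    """Pearson correlation (R, two-sided p) between two per-individual scalars."""
    x = np.asarray(traits, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("traits and phenotypes must be equal-length 1-D vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in traits or phenotypes; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def association_scan(traits, genotypes: GenotypeMatrix, alpha: float = 0.01) -> AssociationResult:
    """Per-SNP OLS of trait on minor-allele count with Bonferroni control.

    Monomorphic markers are reported with beta 0 and p = 1. When the panel
    carries a known causal index, significant hits elsewhere are counted as
    false positives.
    """
    y = np.asarray(traits, dtype=float)
    g = genotypes.calls.astype(float)
    if y.ndim != 1 or len(y) != g.shape[0]:
        raise ValueError(f"got {len(y)} traits for {g.shape[0]} genotype rows")
    n, n_snps = g.shape
    if n < 3:
        raise ValueError("need at least 3 observations for the regression")
    yc = y - y.mean()
    gc = g - g.mean(axis=0, keepdims=True)
    sxx = (gc**2).sum(axis=0)
    poly = sxx > 0
    beta = np.zeros(n_snps)
    tstat = np.zeros(n_snps)
    pvals = np.ones(n_snps)
    sxy = gc.T @ yc
    beta[poly] = sxy[poly] / sxx[poly]
    # residual variance per marker; dof = n - 2
    syy = float((yc**2).sum())
    ss_res = syy - beta * sxy
    ss_res = np.maximum(ss_res, 0.0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(ss_res / dof / np.where(poly, sxx, 1.0))
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    tstat[poly] = t[poly]
    pvals[poly] = 2.0 * stats.t.sf(np.abs(tstat[poly]), dof)
    threshold = alpha / n_snps
    significant = np.flatnonzero(pvals < threshold)
    fp = None
    if genotypes.causal_index is not None:
        fp = int(np.sum(significant != genotypes.causal_index))
    return AssociationResult(
        snp_ids=list(genotypes.snp_ids),
        beta=beta,
        stat=tstat,
        p=pvals,
        alpha=alpha,
        bonferroni_threshold=threshold,
        significant_indices=significant,
        causal_index=genotypes.causal_index,
        false_positive_count=fp,
    )


def embedding_plot(embeddings: pd.DataFrame, out_path=None):
    """PCA scatter of latent points: color = condition, shade = time point.

    Returns the projected coordinates (approximate by construction — latent
    distances are only semantic through the decoder) and writes a PNG when
    ``out_path`` is given.
    """
    zcols = [c for c in embeddings.columns if c.startswith("z")]
    pts = embeddings[zcols].to_numpy(dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 latent points for the embedding plot")
    proj = PCA(n_components=2).fit_transform(pts)
    coords = embeddings[[c for c in ("individual_id", "condition", "timepoint") if c in embeddings.columns]].copy()
    coords["pc1"] = proj[:, 0]
    coords["pc2"] = proj[:, 1]
    if out_path is not None:
        fig, ax = plt.subplots(figsize=(6, 5))
        tmax = max(coords["timepoint"].max(), 1)
        for cond, color in (("treated", "Reds"), ("control", "Blues")):
            sub = coords[coords["condition"] == cond]
            ax.scatter(
                sub["pc1"], sub["pc2"],
                c=0.3 + 0.7 * sub["timepoint"] / tmax,
                cmap=color, vmin=0, vmax=1, s=14, label=cond,
            )
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend()
        ax.set_title("Latent embedding (PCA, darker = later)")
        fig.tight_layout()
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return coords


def manhattan_plot(result: AssociationResult, out_path):
    """-log10(p) by marker index with the dashed Bonferroni line."""
    if len(result.snp_ids) == 0:
        raise ValueError("empty association result")
    logp = -np.log10(np.maximum(result.p, 1e-300))
    fig, ax = plt.subplots(figsize=(8, 3.2))
    ax.scatter(np.arange(len(logp)), logp, s=8, c="steelblue")
    ax.axhline(-np.log10(result.bonferroni_threshold), ls="--", c="k", lw=1)
    if result.causal_index is not None:
        ax.scatter([result.causal_index], [logp[result.causal_index]], s=24, c="crimson", zorder=3)
    ax.set_xlabel("SNP index")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
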