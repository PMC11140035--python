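"""Count-level expression summarisation: CPM, fold changes, Venn, PCA.

Operates on a genes x samples integer count matrix and a group design.  The
workflow mirrors threshold-based exposure screens on pooled bulk RNA-seq:
library-size normalisation to counts per million (CPM) and log2CPM, per-arm
fold changes against the control arm from arm-mean CPM, fold-change threshold
gene lists (e.g. FC > 15), exact Venn partitioning of the four
exposure-vs-control lists, and PCA of gene-centred log2CPM with samples as
observations.  No p-value based differential testing is performed — gene
selection here is deliberately threshold-based.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .phantom import GroupDesign

__all__ = [
    "NormalizedMatrix",
    "PCAResult",
    "VennPartition",
    "validate_counts",
    "cpm_normalize",
    "fold_changes",
    "threshold_gene_lists",
    "venn_partition",
    "run_pca",
]


@dataclass
class NormalizedMatrix:
    """CPM and log2CPM values with the pseudocount that produced them."""

    cpm: pd.DataFrame
    log2cpm: pd.DataFrame
    pseudocount: float


@dataclass
class PCAResult:
    """Sample scores, gene loadings and variance explained per component."""

    scores: pd.DataFrame  # samples x PCs
    loadings: pd.DataFrame  # genes x PCs
    explained_variance_ratio: np.ndarray
    mean_: pd.Series  # per-gene centring offsets


@dataclass
class VennPartition:
    """Exact region partition of up to four gene lists.

    ``region_counts`` maps a sorted tuple of list names (the lists a region's
    genes belong to — and implicitly not to the others) to the number of
    genes exclusive to that region; ``region_members`` holds the genes.
    """

    list_names: tuple[str, ...]
    region_counts: dict[tuple[str, ...], int]
    region_members: dict[tuple[str, ...], frozenset]

    @property
    def central_intersection(self) -> frozenset:
        return self.region_members.get(self.list_names, frozenset())

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene IDs")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample IDs")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return counts


def cpm_normalize(counts: pd.DataFrame, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Counts per million per sample, plus log2(CPM + pseudocount).

    CPM[g, s] = 1e6 * counts[g, s] / library_size[s]; every CPM column sums
    to 1e6 by construction.  A zero library size is an input error, reported
    with the offending sample named.
    """
    validate_counts(counts)
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    cpm = counts * (1e6 / lib)
    log2cpm = np.log2(cpm + pseudocount)
    return NormalizedMatrix(cpm=cpm, log2cpm=log2cpm, pseudocount=pseudocount)


def fold_changes(
    nm: NormalizedMatrix,
    design: GroupDesign,
    reference_arm: str = "control",
    timepoint: str | None = None,
) -> pd.DataFrame:
    """Per-gene fold changes of each arm against the reference arm.

    FC = (arm-mean CPM + pseudocount) / (reference-mean CPM + pseudocount),
    computed from arm-mean CPM (samples are pooled-organoid libraries).
    Returns a tidy table with columns gene, arm, mean_cpm, mean_cpm_ref,
    fc, log2fc, direction.
    """
    ref_samples = design.samples_in(reference_arm, timepoint)
    if not ref_samples:
        raise ValueError(f"reference arm {reference_arm!r} has no samples")
    pc = nm.pseudocount
    ref_mean = nm.cpm[ref_samples].mean(axis=1)
    rows = []
    arms = [a for a in design.table["arm"].unique() if a != reference_arm]
    for arm in arms:
        samp = design.samples_in(arm, timepoint)
        if not samp:
            raise ValueError(f"arm {arm!r} has no samples")
        arm_mean = nm.cpm[samp].mean(axis=1)
        fc = (arm_mean + pc) / (ref_mean + pc)
        log2fc = np.log2(fc)
        rows.append(
            pd.DataFrame(
                {
                    "gene": nm.cpm.index,
                    "arm": arm,
                    "mean_cpm": arm_mean.to_numpy(),
                    "mean_cpm_ref": ref_mean.to_numpy(),
                    "fc": fc.to_numpy(),
                    "log2fc": log2fc.to_numpy(),
                    "direction": np.sign(log2fc.to_numpy()).astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def threshold_gene_lists(
    de: pd.DataFrame, threshold_fc: float = 15.0
) -> dict[str, dict[str, list[str]]]:
    """Per-arm up/down gene lists at a fold-change threshold.

    Up lists hold genes with FC > threshold, down lists FC < 1/threshold;
    the two directions are reported separately.
    """
    if threshold_fc <= 1:
        raise ValueError("threshold_fc must exceed 1")
    out: dict[str, dict[str, list[str]]] = {}
    for arm, sub in de.groupby("arm", sort=False):
        out[arm] = {
            "up": sorted(sub.loc[sub["fc"] > threshold_fc, "gene"]),
            "down": sorted(sub.loc[sub["fc"] < 1.0 / threshold_fc, "gene"]),
        }
    return out


def venn_partition(lists: dict[str, set | list]) -> VennPartition:
    """Exact Venn region partition of 2-4 named gene lists.

    Every gene in the union is assigned to exactly the region of lists that
    contain it, so region counts sum to the union size.
    """
    if not 2 <= len(lists) <= 4:
        raise ValueError("venn_partition takes 2-4 lists")
    sets = {name: set(v) for name, v in lists.items()}
    names = tuple(sets)
    counts: dict[tuple[str, ...], int] = {}
    members: dict[tuple[str, ...], frozenset] = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            region = set.intersection(*(sets[n] for n in inside))
            for n in names:
                if n not in inside:
                    region -= sets[n]
            counts[inside] = len(region)
            members[inside] = frozenset(region)
    return VennPartition(list_names=names, region_counts=counts, region_members=members)


def run_pca(
    nm: NormalizedMatrix,
    design: GroupDesign | None = None,
    n_components: int | None = None,
    top_n_genes: int | None = None,
) -> PCAResult:
    """PCA of gene-centred log2CPM with samples as observations.

    Genes are centred but not unit-scaled, so high-variance transcripts drive
    the leading components.  Signs follow a deterministic convention: the
    largest-magnitude loading of each component is made positive.  With
    ``top_n_genes`` the analysis is restricted to the most variable genes.
    """
    X = nm.log2cpm
    if X.shape[1] < 2:
        raise ValueError("PCA requires >= 2 samples")
    if top_n_genes is not None:
        keep = X.var(axis=1).nlargest(top_n_genes).index
        X = X.loc[keep]
    samples = X.columns
    genes = X.index
    M = X.to_numpy().T  # samples x genes
    mean = M.mean(axis=0)
    Mc = M - mean
    U, S, Vt = np.linalg.svd(Mc, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    n = M.shape[0]
    var = S**2 / (n - 1)
    total = Mc.var(axis=0, ddof=1).sum()
    evr = var / total if total > 0 else np.zeros_like(var)
    if n_components is not None:
        U, S, Vt, evr = U[:, :n_components], S[:n_components], Vt[:n_components], evr[:n_components]
    pcs = [f"PC{i + 1}" for i in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(U * S, index=samples, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=genes, columns=pcs),
        explained_variance_ratio=evr,
        mean_=pd.Series(mean, index=genes),
    )
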