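"""Consensus-NMF discovery of recurrent tumor expression metaprograms.

Per sample, a rank-10 non-negative matrix factorization of the (clipped
non-negative) cells x genes matrix yields factor signatures — the top
100 genes of each factor by loading.  Signatures pooled across samples
are hierarchically clustered under the 1 - Jaccard distance between
their gene sets; clusters supported by at least two samples are the
recurrent metaprograms.  Each program is scored per cell as the mean
expression of its consensus genes and refined to the 30 genes most
correlated with that score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF

from .io_core import ValidationError

__all__ = [
    "FactorSignature",
    "Metaprogram",
    "fit_nmf_sample",
    "jaccard_distance",
    "consensus_cluster",
    "score_cells",
    "refine_program",
]


@dataclass
class FactorSignature:
    """Top genes of one NMF factor in one sample, ordered by loading."""

    sample_id: str
    factor_id: int
    genes: list[str]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("signature genes must be unique")


@dataclass
class Metaprogram:
    """A cluster of factor signatures recurring across samples."""

    program_id: int
    members: list[FactorSignature]
    consensus_genes: list[str]
    recurrent: bool
    refined_genes: list[str] | None = None

    @property
    def member_samples(self) -> set[str]:
        return {m.sample_id for m in self.members}


def _as_matrix(expr) -> tuple[np.ndarray, list[str], pd.Index]:
    if isinstance(expr, pd.DataFrame):
        return expr.to_numpy(dtype=float), list(expr.columns), expr.index
    arr = np.asarray(expr, dtype=float)
    return arr, [f"g{j}" for j in range(arr.shape[1])], pd.RangeIndex(arr.shape[0])


def fit_nmf_sample(
    expr,
    sample_id: str = "S",
    rank: int = 10,
    top: int = 100,
    seed: int = 0,
    max_iter: int = 500,
) -> list[FactorSignature]:
    """Rank-``rank`` NMF of one sample's cells x genes matrix.

    Negative entries are clipped to 0 before factorization.  Each factor
    yields a signature of its ``top`` genes ranked by gene loading
    (ties broken by gene name for determinism).
    """
    X, genes, _ = _as_matrix(expr)
    X = np.clip(X, 0, None)
    if X.sum() == 0:
        raise ValidationError("all-zero expression matrix: NMF undefined")
    if min(X.shape) < rank:
        raise ValidationError(f"need at least {rank} cells and genes for rank {rank}")
    model = NMF(n_components=rank, init="nndsvda", random_state=seed, max_iter=max_iter)
    model.fit(X)
    H = model.components_  # (rank, genes)
    n_top = min(top, len(genes))
    gene_arr = np.array(genes)
    sigs = []
    for f in range(rank):
        order = np.lexsort((gene_arr, -H[f]))
        sigs.append(
            FactorSignature(sample_id=sample_id, factor_id=f, genes=list(gene_arr[order[:n_top]]))
        )
    return sigs


def jaccard_distance(a, b) -> float:
    """1 - |A intersect B| / |A union B| over gene sets (0 for two empties)."""
    A, B = set(a), set(b)
    union = A | B
    if not union:
        return 0.0
    return 1.0 - len(A & B) / len(union)


def consensus_cluster(
    signatures: list[FactorSignature],
    n_programs: int | None = None,
    cut_height: float | None = None,
    linkage_method: str = "average",
    min_samples_recurrent: int = 2,
    consensus_frac: float = 0.5,
) -> list[Metaprogram]:
    """Agglomerative clustering of factor signatures under 1 - Jaccard.

    Cut either at ``n_programs`` clusters or at ``cut_height``.  A
    cluster is marked recurrent when its members come from at least
    ``min_samples_recurrent`` distinct samples.  Its consensus gene set
    collects genes present in at least ``consensus_frac`` of member
    signatures, ordered by (frequency desc, name).
    """
    if len(signatures) < 2:
        raise ValidationError("need at least 2 signatures to cluster")
    if n_programs is not None and n_programs > len(signatures):
        raise ValidationError("n_programs exceeds the number of signatures")
    if (n_programs is None) == (cut_height is None):
        raise ValidationError("specify exactly one of n_programs or cut_height")

    n = len(signatures)
    D = np.zeros((n, n))
    sets = [set(s.genes) for s in signatures]
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = jaccard_distance(sets[i], sets[j])
    Z = linkage(squareform(D, checks=False), method=linkage_method)
    if n_programs is not None:
        labels = fcluster(Z, t=n_programs, criterion="maxclust")
    else:
        labels = fcluster(Z, t=cut_height, criterion="distance")

    programs = []
    for pid in sorted(np.unique(labels)):
        members = [signatures[i] for i in np.flatnonzero(labels == pid)]
        freq: dict[str, int] = {}
        for m in members:
            for g in m.genes:
                freq[g] = freq.get(g, 0) + 1
        cutoff = consensus_frac * len(members)
        consensus = sorted(
            (g for g, c in freq.items() if c >= cutoff),
            key=lambda g: (-freq[g], g),
        )
        programs.append(
            Metaprogram(
                program_id=int(pid),
                members=members,
                consensus_genes=consensus,
                recurrent=len({m.sample_id for m in members}) >= min_samples_recurrent,
            )
        )
    return programs


def score_cells(expr, gene_set) -> pd.Series:
    """Mean expression of the signature genes, per cell.

    Signature genes absent from the matrix are dropped with a warning;
    zero overlap is an error (nothing to average).
    """
    X, genes, index = _as_matrix(expr)
    wanted = list(gene_set)
    present = [g for g in wanted if g in set(genes)]
    if not present:
        raise ValidationError(f"no signature genes present in the matrix: {sorted(wanted)}")
    missing = sorted(set(wanted) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} signature gene(s) missing, scored without them: {missing[:5]}...")
    col = {g: j for j, g in enumerate(genes)}
    cols = [col[g] for g in present]
    return pd.Series(X[:, cols].mean(axis=1), index=index, name="score")


def refine_program(mp: Metaprogram, expr, top: int = 30) -> Metaprogram:
    """Redefine a program by its ``top`` feature genes: candidates are the
    union of member-signature genes, ranked by Pearson correlation of
    their expression with the program's expression score across cells
    (ties broken by gene name)."""
    X, genes, _ = _as_matrix(expr)
    score = score_cells(expr, mp.consensus_genes).to_numpy()
    if np.std(score) == 0:
        raise ValidationError("program score is constant: correlations undefined")
    col = {g: j for j, g in enumerate(genes)}
    candidates = sorted({g for m in mp.members for g in m.genes if g in col})
    s = (score - score.mean()) / score.std()
    corrs = []
    for g in candidates:
        v = X[:, col[g]]
        sd = v.std()
        r = 0.0 if sd == 0 else float(np.mean(s * (v - v.mean()) / sd))
        corrs.append((g, r))
    corrs.sort(key=lambda t: (-t[1], t[0]))
    mp.refined_genes = [g for g, _ in corrs[:top]]
    return mp
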