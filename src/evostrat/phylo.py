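"""Cross-species similarity scores and phylogenetically controlled regression.

Continuous traits use phylogenetic generalized least squares (PGLS) with the
Brownian-motion covariance ``C[i, j] = shared root-to-MRCA branch length``.
Binary traits (e.g. vocal learning) use a phylogenetic logistic regression in
the Ives-Garland spirit: quasi-likelihood logistic estimating equations whose
working residual correlation follows a mean-reverting (rate ``alpha``)
transformation of the tree, ``R(alpha)[i, j] = exp(-alpha * d_ij / T)`` with
``d_ij`` the patristic distance and ``T`` the tree height.  ``alpha`` is
selected on a grid by a Gaussian quasi-likelihood criterion; as
``alpha -> inf`` the working correlation becomes the identity and the
estimator reduces exactly to ordinary logistic regression, which is the
correctness anchor (no claim of numerical equivalence to any particular
published estimator is made).

The per-species *annotation similarity score* is the z-score of that
species' mean percent identity to the human annotation regions against its
identity to a genome-background region panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhyloModelResult",
    "load_tree",
    "bm_covariance",
    "patristic_distances",
    "percent_identity",
    "similarity_scores",
    "pgls",
    "phylo_logistic",
]

DEFAULT_ALPHA_GRID = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, np.inf)


@dataclass
class PhyloModelResult:
    """Phylogenetic regression summary."""

    terms: pd.DataFrame  # term, beta, se, p
    model: str  # "pgls" | "phylo_logistic"
    n: int
    alpha: float | None = None

    def coef(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "beta"])


def load_tree(tree):
    """Accept a dendropy Tree, a newick string, or a path to a newick file."""
    import dendropy

    if isinstance(tree, dendropy.Tree):
        return tree
    text = str(tree)
    if "(" not in text:  # looks like a path
        text = Path(text).read_text()
    return dendropy.Tree.get(data=text, schema="newick")


def _leaf_info(tree):
    """Leaf names, root-to-leaf depths, and leaf nodes; validates names."""
    names, depths, leaves = [], [], []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree contains an unnamed leaf")
        names.append(leaf.taxon.label)
        depths.append(leaf.distance_from_root())
        leaves.append(leaf)
    if len(set(names)) != len(names):
        raise ValueError("leaf names must be unique")
    return names, np.asarray(depths, dtype=float), leaves


def patristic_distances(tree) -> tuple[np.ndarray, list[str]]:
    """Pairwise patristic (branch-length path) distance matrix and leaf order."""
    tree = load_tree(tree)
    names, _, _ = _leaf_info(tree)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[names[i]], taxa[names[j]])
            D[i, j] = D[j, i] = d
    return D, names


def bm_covariance(tree) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance: shared root-to-MRCA path length per pair.

    ``C[i, i]`` is the root-to-leaf depth; for ``i != j``,
    ``C[i, j] = (depth_i + depth_j - d_ij) / 2`` where ``d_ij`` is the
    patristic distance.  Ultrametricity is not required.
    """
    tree = load_tree(tree)
    names, depths, _ = _leaf_info(tree)
    D, names2 = patristic_distances(tree)
    assert names == names2
    C = (depths[:, None] + depths[None, :] - D) / 2.0
    np.fill_diagonal(C, depths)
    C = np.clip(C, 0.0, None)
    return C, names


# ---------------------------------------------------------------------------
# Sequence similarity


def percent_identity(aln_a: str, aln_b: str) -> tuple[float, int]:
    """Fraction of matching bases over gap-free aligned columns.

    Returns ``(identity, n_columns)``; ``n_columns`` is 0 for all-gap pairs.
    """
    if len(aln_a) != len(aln_b):
        raise ValueError("aligned sequences must have equal length")
    a = np.frombuffer(aln_a.upper().encode(), dtype="S1")
    b = np.frombuffer(aln_b.upper().encode(), dtype="S1")
    keep = (a != b"-") & (b != b"-")
    n = int(keep.sum())
    if n == 0:
        return float("nan"), 0
    return float((a[keep] == b[keep]).mean()), n


def read_alignment_fasta(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read per-region pairwise alignments from a single aligned FASTA.

    Records come in pairs named ``<region_id>|human`` and
    ``<region_id>|<species>``; returns region_id -> (human_seq, species_seq).
    """
    from Bio import SeqIO

    by_region: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        region, _, who = rec.id.partition("|")
        by_region.setdefault(region, {})[("human" if who == "human" else "species")] = str(rec.seq)
    out = {}
    for region, pair in by_region.items():
        if set(pair) != {"human", "species"}:
            raise ValueError(f"region {region!r}: expected a human/species record pair")
        out[region] = (pair["human"], pair["species"])
    return out


def similarity_scores(
    per_region_alignments: Mapping[str, Mapping[str, tuple[str, str]]],
    annotation_ids: Sequence[str],
    background_ids: Sequence[str],
    min_regions: int = 3,
) -> pd.DataFrame:
    """Per-species annotation-likeness score from pairwise alignments.

    ``per_region_alignments[species][region_id] = (human_aln, species_aln)``.
    Per region, percent identity is matches over gap-free columns; regions
    with zero aligned columns are excluded (and counted).  The score is
    ``(mean identity over annotation regions - mean over background) /
    SD over background``; species contributing fewer than ``min_regions``
    regions in either panel get a NaN score.
    """
    rows = []
    for species, regions in per_region_alignments.items():
        ann, bg, excluded = [], [], 0
        for rid, (h, s) in regions.items():
            ident, ncol = percent_identity(h, s)
            if ncol == 0:
                excluded += 1
                continue
            if rid in annotation_ids:
                ann.append(ident)
            elif rid in background_ids:
                bg.append(ident)
        n_used = len(ann) + len(bg)
        if len(ann) < min_regions or len(bg) < min_regions:
            score = float("nan")
        else:
            sd = np.std(bg, ddof=1)
            diff = float(np.mean(ann) - np.mean(bg))
            score = diff / sd if sd > 0 else (0.0 if diff == 0 else float("inf"))
        rows.append(
            {
                "species": species,
                "score": score,
                "n_regions": n_used,
                "n_excluded": excluded,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phylogenetic regression


def _design_matrix(predictors: pd.DataFrame) -> pd.DataFrame:
    X = predictors.astype(float).copy()
    X.insert(0, "const", 1.0)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("singular design matrix (constant or collinear predictor)")
    return X


def pgls(response, predictors: pd.DataFrame, C: np.ndarray) -> PhyloModelResult:
    """Phylogenetic generalized least squares under Brownian covariance.

    ``beta = (X' C^-1 X)^-1 X' C^-1 y`` with standard errors from
    ``sigma2 * (X' C^-1 X)^-1``.  On a star tree (diagonal C with equal
    entries) this reduces to ordinary least squares.
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    X = _design_matrix(pd.DataFrame(predictors))
    C = np.asarray(C, dtype=float)
    if C.shape != (len(y), len(y)):
        raise ValueError("covariance matrix shape does not match the species table")
    # tolerate floating-point PSD slack, but reject genuinely singular trees
    jitter = 1e-10 * float(np.mean(np.diag(C)))
    C = C + jitter * np.eye(len(y))
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        raise ValueError(
            "phylogenetic covariance is singular; check for zero branch lengths "
            "or duplicated tips"
        ) from None
    fit = sm.GLS(y, X, sigma=C).fit()
    rows = [
        {"term": t, "beta": float(fit.params[t]), "se": float(fit.bse[t]), "p": float(fit.pvalues[t])}
        for t in X.columns
        if t != "const"
    ]
    return PhyloModelResult(terms=pd.DataFrame(rows), model="pgls", n=len(y))


def _expit(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))


def _gee_logistic(y: np.ndarray, X: np.ndarray, R: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Quasi-Fisher scoring for logistic estimating equations with working
    correlation R.  With R = I this is exactly logistic-regression IRLS."""
    n, k = X.shape
    beta = np.zeros(k)
    try:
        R_inv = np.linalg.inv(R + 1e-10 * np.eye(n))
    except np.linalg.LinAlgError:
        return None  # this alpha yields a singular working correlation
    for it in range(max_iter):
        eta = X @ beta
        mu = _expit(eta)
        a = np.sqrt(np.clip(mu * (1 - mu), 1e-12, None))
        # D = diag(a^2) X ; V = diag(a) R diag(a)
        Xa = X * a[:, None]
        Vinv_r = (R_inv @ ((y - mu) / a)) / a
        H = Xa.T @ R_inv @ Xa  # D' V^-1 D
        score = X.T @ (mu * (1 - mu) * Vinv_r)
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            return None
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        return None
    eta = X @ beta
    mu = _expit(eta)
    a = np.sqrt(np.clip(mu * (1 - mu), 1e-12, None))
    pearson = (y - mu) / a
    phi = float(pearson @ R_inv @ pearson) / max(n - k, 1)
    Xa = X * a[:, None]
    cov = phi * np.linalg.inv(Xa.T @ R_inv @ Xa)
    sign, logdet_R = np.linalg.slogdet(R)
    # Gaussian quasi-log-likelihood on the Pearson-residual scale
    ql = -0.5 * (n * np.log(max(phi, 1e-12)) + logdet_R + (pearson @ R_inv @ pearson) / max(phi, 1e-12))
    return {"beta": beta, "cov": cov, "phi": phi, "ql": float(ql), "n_iter": it + 1}


def phylo_logistic(
    binary_response,
    predictors: pd.DataFrame,
    tree,
    alpha_grid: Sequence[float] | None = None,
) -> PhyloModelResult:
    """Phylogenetic logistic regression for a binary species trait.

    The working residual correlation is ``R(alpha) = exp(-alpha * D / T)``
    with ``D`` the patristic distance matrix and ``T`` the tree height;
    ``alpha = inf`` (always worth including in the grid) gives the identity
    and recovers standard logistic regression.  ``alpha`` is chosen on the
    grid by maximizing a Gaussian quasi-likelihood of the Pearson residuals;
    the reported p-values are Wald tests with model-based covariance.
    """
    y = np.asarray(binary_response, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binary response must be 0/1")
    if y.min() == y.max():
        raise ValueError("response is all 0 or all 1")
    Xdf = _design_matrix(pd.DataFrame(predictors))
    X = Xdf.to_numpy(dtype=float)
    D, names = patristic_distances(tree)
    if len(names) != len(y):
        raise ValueError("tree tip count does not match response length")
    T = float(D.max()) / 2.0 if D.max() > 0 else 1.0
    if alpha_grid is None:
        alpha_grid = DEFAULT_ALPHA_GRID

    fits = {}
    for alpha in alpha_grid:
        if np.isinf(alpha):
            R = np.eye(len(y))
        else:
            R = np.exp(-alpha * D / T)
        res = _gee_logistic(y, X, R)
        if res is not None:
            fits[alpha] = res
    if not fits:
        raise RuntimeError(
            f"phylogenetic logistic regression failed to converge for every alpha "
            f"in the grid {tuple(alpha_grid)}"
        )
    alpha_best = max(fits, key=lambda a: fits[a]["ql"])
    best = fits[alpha_best]
    se = np.sqrt(np.diag(best["cov"]))
    z = best["beta"] / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    rows = [
        {"term": t, "beta": float(b), "se": float(s), "p": float(pv)}
        for t, b, s, pv in zip(Xdf.columns, best["beta"], se, p)
        if t != "const"
    ]
    return PhyloModelResult(
        terms=pd.DataFrame(rows), model="phylo_logistic", n=len(y), alpha=float(alpha_best)
    )
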