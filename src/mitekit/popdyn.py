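"""Insertional-polymorphism scoring and population clustering.

Site-specific presence/absence of each insertion is genotyped by in-silico
PCR amplicon sizes, summarized per population with 0/1/2 codes (empty in
all / polymorphic / full in all accessions), and accessions are clustered
on Bray-Curtis dissimilarity with group-average linkage. Cluster structure
is tested top-down with the SIMPROF permutation test: the sorted vector of
pairwise similarities (the resemblance profile) is compared, via the pi
statistic, against a mean profile built from column-permuted null data.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._util import hamming, revcomp

#: published 11-locus presence/absence code panel across five wild-emmer
#: populations (Mt. Hermon, Amiad, Tabgha, Jaba, Mt. Amasa) and bread wheat;
#: 0 = empty site in all accessions, 1 = full site in some, 2 = full in all.
EMMER_PANEL_CODES: dict[str, tuple[int, ...]] = {
    "A2-MH": (1, 0, 0, 0, 0, 0),
    "A4-1":  (0, 1, 1, 0, 0, 1),
    "A4-4":  (1, 1, 1, 1, 1, 0),
    "A5-6":  (2, 2, 2, 2, 2, 2),
    "A6-2":  (0, 1, 1, 0, 0, 0),
    "A7-5":  (0, 1, 1, 0, 1, 0),
    "B1-2":  (0, 0, 0, 0, 0, 2),
    "B1-4":  (1, 1, 2, 1, 1, 1),
    "B3-4":  (0, 1, 1, 0, 0, 0),
    "B7-4":  (0, 1, 1, 1, 0, 0),
    "B7-6":  (0, 1, 1, 0, 0, 0),
}

PANEL_COLUMNS = ("MtHermon", "Amiad", "Tabgha", "Jaba", "MtAmasa", "BreadWheat")


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str  # 5'->3' on the opposite strand
    locus_id: str = ""
    expected_full: int | None = None
    expected_empty: int | None = None

    def __post_init__(self) -> None:
        if min(len(self.forward), len(self.reverse)) < 15:
            raise ValueError("primers must be >= 15 nt")


@dataclass
class SimprofResult:
    node_id: int
    members: tuple[str, ...]
    pi: float
    p_value: float
    n_mean_perms: int
    n_null_perms: int
    significant: bool


def insilico_pcr(template: str, primers: PrimerPair, max_mismatch: int = 0,
                 max_product_size: int = 5000,
                 three_prime_exact: int = 3) -> list[tuple[int, int, int]]:
    """All amplicons from a primer pair on one template strand.

    A product is reported for every forward-primer match paired with every
    downstream reverse-complemented reverse-primer match within
    ``max_product_size``; length includes both primers. When mismatches are
    allowed, the 3'-terminal ``three_prime_exact`` bases of each primer
    must still match exactly.
    """
    if not template:
        raise ValueError("template must be non-empty")
    fwd, rev_rc = primers.forward, revcomp(primers.reverse)

    def matches(primer: str, protect_left: bool) -> list[int]:
        L = len(primer)
        out = []
        for i in range(len(template) - L + 1):
            window = template[i:i + L]
            if max_mismatch == 0:
                if window == primer:
                    out.append(i)
                continue
            if hamming(window, primer) > max_mismatch:
                continue
            # 3' end of the forward primer = right end of its match;
            # 3' end of the reverse primer = left end of the rev-comp match
            tail = (window[:three_prime_exact], primer[:three_prime_exact]) \
                if protect_left else \
                (window[-three_prime_exact:], primer[-three_prime_exact:])
            if tail[0] == tail[1]:
                out.append(i)
        return out

    fwd_sites = matches(fwd, protect_left=False)
    rev_sites = matches(rev_rc, protect_left=True)
    products = []
    for i in fwd_sites:
        for j in rev_sites:
            if j < i + len(fwd):
                continue
            end = j + len(rev_rc)
            if end - i <= max_product_size:
                products.append((i, end, end - i))
    return products


def score_locus(amplicons_by_accession: dict[str, list[int]],
                expected_full: int, expected_empty: int, tol: int = 10
                ) -> tuple[dict[str, int], set[str]]:
    """Binary full/empty call per accession from observed product sizes.

    Returns (calls, unscored). A full-size product wins over an empty-size
    one (presence); accessions whose products match neither size are
    flagged unscored and excluded from population codes.
    """
    if abs(expected_full - expected_empty) <= 2 * tol:
        raise ValueError("expected sizes must differ by more than 2*tol")
    calls: dict[str, int] = {}
    unscored: set[str] = set()
    for acc, sizes in amplicons_by_accession.items():
        has_full = any(abs(s - expected_full) <= tol for s in sizes)
        has_empty = any(abs(s - expected_empty) <= tol for s in sizes)
        if has_full:
            calls[acc] = 1
        elif has_empty:
            calls[acc] = 0
        else:
            unscored.add(acc)
    return calls, unscored


def population_codes(calls: pd.DataFrame) -> pd.DataFrame:
    """0/1/2 summary codes per locus x population.

    `calls` has columns locus_id, accession_id, population, call (0/1).
    Code 0 iff all accessions empty, 2 iff all full, 1 otherwise.
    """
    def code(x: pd.Series) -> int:
        if (x == 1).all():
            return 2
        if (x == 0).all():
            return 0
        return 1

    wide = calls.pivot_table(index="locus_id", columns="population",
                             values="call", aggfunc=code)
    return wide.astype(int)


def panel_codes_frame() -> pd.DataFrame:
    """The published code panel as a loci x populations DataFrame."""
    return pd.DataFrame.from_dict(EMMER_PANEL_CODES, orient="index",
                                  columns=list(PANEL_COLUMNS))


def summarize_codes(codes: pd.DataFrame, emmer_columns: list[str],
                    outgroup_column: str,
                    index_loci: tuple[str, ...] = ()) -> dict:
    """Panel-level summary of a 0/1/2 code matrix.

    Counts loci fixed present everywhere, and loci absent from the
    outgroup (bread wheat) yet polymorphic (code 1) in at least two of the
    listed populations, excluding any separately described index loci.
    """
    fixed = codes[(codes == 2).all(axis=1)].index.tolist()
    mask = (codes[outgroup_column] == 0) & \
           ((codes[emmer_columns] == 1).sum(axis=1) >= 2)
    specific = [l for l in codes.index[mask] if l not in index_loci]
    absent_emmer_present_out = codes[
        (codes[emmer_columns] == 0).all(axis=1) & (codes[outgroup_column] > 0)
    ].index.tolist()
    return {
        "n_loci": int(len(codes)),
        "fixed_present": fixed,
        "n_fixed_present": len(fixed),
        "outgroup_absent_polymorphic": specific,
        "n_outgroup_absent_polymorphic": len(specific),
        "emmer_absent_outgroup_present": absent_emmer_present_out,
    }


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Accession x accession Bray-Curtis dissimilarity of a loci profile.

    d(i,j) = sum|x_ik - x_jk| / sum(x_ik + x_jk); an all-zero pair has no
    defined denominator and is set to 1 with a warning. On binary data this
    equals one minus the Sorensen similarity.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two accessions")
    X = matrix.to_numpy(dtype=float)
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    if (den[np.triu_indices_from(den, 1)] == 0).any():
        warnings.warn("all-zero accession pair: dissimilarity defined as 1")
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def cluster(dissimilarity: pd.DataFrame) -> np.ndarray:
    """Group-average (UPGMA) agglomerative clustering; returns a scipy
    linkage matrix over the accession order of the input."""
    d = dissimilarity.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    return hierarchy.linkage(squareform(d, checks=False), method="average")


def _bc_profiles(X: np.ndarray) -> np.ndarray:
    """Sorted pairwise Bray-Curtis *similarity* profiles, batched.

    X has shape (B, n, loci); returns (B, n*(n-1)/2) sorted ascending.
    """
    s = X.sum(axis=2)
    inter = np.einsum("bil,bjl->bij", X, X)
    den = s[:, :, None] + s[:, None, :]
    num = den - 2 * inter  # sum|x-y| for binary data
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1), 1.0)
    iu = np.triu_indices(X.shape[1], 1)
    sims = 1.0 - d[:, iu[0], iu[1]]
    sims.sort(axis=1)
    return sims


def simprof_node(data: np.ndarray, n_mean_perms: int = 1000,
                 n_null_perms: int = 999, seed: int = 0
                 ) -> tuple[float, float]:
    """pi statistic and permutation p-value for one node's accessions.

    `data` is the binary loci matrix restricted to the node (n x loci).
    Null matrices permute each locus column independently across the
    node's accessions; the mean profile is the rank-wise mean over
    ``n_mean_perms`` null profiles; pi is the L1 deviation of a profile
    from the mean profile; p = (1 + #{null pi >= observed}) / (1 + n_null).
    """
    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("SIMPROF needs at least three accessions")
    rng = np.random.default_rng(seed)
    B = n_mean_perms + n_null_perms
    tile = np.broadcast_to(X, (B, *X.shape)).copy()
    perms = rng.permuted(tile, axis=1)  # each column shuffled independently
    profiles = _bc_profiles(perms)
    mean_profile = profiles[:n_mean_perms].mean(axis=0)
    actual = _bc_profiles(X[None])[0]
    pi = float(np.abs(actual - mean_profile).sum())
    null_pi = np.abs(profiles[n_mean_perms:] - mean_profile).sum(axis=1)
    p = (1.0 + int((null_pi >= pi).sum())) / (1.0 + n_null_perms)
    return pi, p


def simprof(matrix: pd.DataFrame, linkage: np.ndarray | None = None,
            alpha: float = 0.05, n_mean_perms: int = 1000,
            n_null_perms: int = 999, seed: int = 0) -> list[SimprofResult]:
    """Top-down SIMPROF along the dendrogram of a presence/absence matrix.

    Children of a non-significant node are not tested (they are treated as
    homogeneous); nodes with fewer than three accessions auto-pass as
    non-significant. Results are invariant to accession ordering: each
    node's permutation stream is seeded from a content hash of its member
    profiles combined with `seed`.
    """
    labels = list(matrix.index)
    if linkage is None:
        linkage = cluster(bray_curtis(matrix))
    tree = hierarchy.to_tree(linkage)
    X_all = matrix.to_numpy(dtype=float)
    results: list[SimprofResult] = []

    def visit(node) -> None:
        members = sorted(node.pre_order(lambda leaf: leaf.id))
        member_labels = tuple(labels[i] for i in members)
        # sort rows by label so the draw does not depend on input order
        order = sorted(range(len(members)),
                       key=lambda k: str(member_labels[k]))
        X = X_all[[members[k] for k in order]]
        if len(members) < 3:
            results.append(SimprofResult(node.id, member_labels, 0.0, 1.0,
                                         n_mean_perms, n_null_perms, False))
            return
        node_seed = (seed + zlib.crc32(X.astype(np.int8).tobytes())) % (2**31 - 1)
        pi, p = simprof_node(X, n_mean_perms, n_null_perms, node_seed)
        significant = p < alpha
        results.append(SimprofResult(node.id, member_labels, pi, p,
                                     n_mean_perms, n_null_perms, significant))
        if significant and not node.is_leaf():
            visit(node.left)
            visit(node.right)

    visit(tree)
    return results


def dendrogram_newick(linkage: np.ndarray, labels: list[str],
                      results: list[SimprofResult] | None = None) -> str:
    """Newick export of the dendrogram; SIMPROF p-values, when given, are
    attached to internal nodes as comments."""
    pmap = {r.node_id: r.p_value for r in results or []}
    tree = hierarchy.to_tree(linkage)

    def fmt(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        inner = ",".join(fmt(c, node.dist) for c in (node.left, node.right))
        comment = f"[&&p={pmap[node.id]:.4g}]" if node.id in pmap else ""
        return f"({inner}){comment}:{length:.6g}"

    return fmt(tree, tree.dist).rsplit(":", 1)[0] + ";"
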