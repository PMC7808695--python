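"""Pseudohaploid population genomics.

Low-coverage ancient genomes cannot be genotyped diploid; instead one
high-quality allele is sampled per covered SNP ("pseudohaploid" calls).
This module implements that sampling, identity-by-state (IBS) distances
(1 - p(IBS)) with classical (Torgerson) MDS for clustering, and unsupervised
admixture estimation: a binomial-likelihood model with individual ancestry
fractions Q and component allele frequencies F, fitted by EM
(block-relaxation) with replicate mode alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -1

_PURINES = frozenset("AG")


def is_transversion(ref: str, alt: str) -> bool:
    """True when ref/alt is a purine<->pyrimidine change (deamination-proof)."""
    return (ref in _PURINES) != (alt in _PURINES)


@dataclass
class SitePanel:
    """Biallelic SNP sites plus diploid reference-individual genotypes.

    ``sites`` columns: contig, pos (1-based), ref, alt, is_transversion.
    ``genotypes``: individuals x sites array of alt-allele dosages in
    {0,1,2}, -1 for missing. ``labels`` maps individual -> population.
    ``x_sites`` optionally carries X-chromosome contamination-informative
    sites (columns contig, pos, ref, alt, f).
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    individuals: list
    labels: dict
    x_sites: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if self.genotypes.shape != (len(self.individuals), len(self.sites)):
            raise ValueError("genotype matrix shape does not match individuals x sites")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self) -> dict:
        """(contig, pos) -> column index lookup."""
        return {(c, int(p)): i
                for i, (c, p) in enumerate(zip(self.sites["contig"], self.sites["pos"]))}


@dataclass
class PseudohaploidGenotypes:
    """One sampled allele per covered panel site for one ancient sample."""

    sample_id: str
    calls: np.ndarray  # int8 per panel site: 0 ref, 1 alt, -1 missing

    @property
    def n_covered(self) -> int:
        return int(np.sum(self.calls != MISSING))


@dataclass
class IBSMatrix:
    individuals: list
    p_ibs: np.ndarray
    overlap: np.ndarray
    min_overlap: int

    @property
    def distance(self) -> np.ndarray:
        return 1.0 - self.p_ibs

    @property
    def flagged(self) -> np.ndarray:
        """Pairs whose overlap falls below the floor (distance unreliable)."""
        f = self.overlap < self.min_overlap
        np.fill_diagonal(f, False)
        return f


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray
    F: np.ndarray
    loglik: float
    loglik_trace: np.ndarray
    seed: int
    converged: bool
    n_iter: int


def pseudohaploid_call(rs, panel: SitePanel, min_mapq: int = 30, min_bq: int = 30,
                       seed: int = 0) -> PseudohaploidGenotypes:
    """Sample one passing allele per covered panel site.

    At each site, reads with mapping quality >= ``min_mapq`` contribute their
    base if its quality >= ``min_bq`` and it equals the site's ref or alt
    allele; one contributing base is then drawn uniformly. Sites with no
    passing ref/alt base are missing.
    """
    rng = np.random.default_rng(seed)
    idx = panel.site_index()
    # bucket candidate alleles per site
    alleles: dict = {}
    refs = panel.sites["ref"].to_numpy()
    alts = panel.sites["alt"].to_numpy()
    by_contig: dict = {}
    for key, j in idx.items():
        by_contig.setdefault(key[0], []).append((key[1], j))
    pos_maps = {c: dict(v) for c, v in by_contig.items()}
    for r in rs.reads:
        pm = pos_maps.get(r.contig)
        if pm is None or r.mapq < min_mapq:
            continue
        for off in range(len(r.seq)):
            j = pm.get(r.start + off)
            if j is None or r.quals[off] < min_bq:
                continue
            b = r.seq[off]
            if b == refs[j]:
                alleles.setdefault(j, []).append(0)
            elif b == alts[j]:
                alleles.setdefault(j, []).append(1)
    calls = np.full(panel.n_sites, MISSING, dtype=np.int8)
    for j in sorted(alleles):
        opts = alleles[j]
        calls[j] = opts[rng.integers(len(opts))]
    return PseudohaploidGenotypes(rs.sample_id, calls)


def coverage_report(g: PseudohaploidGenotypes, panel_size: int) -> tuple[int, float]:
    """Covered-site count and percent of the panel, rounded to 1 decimal."""
    if panel_size <= 0:
        raise ValueError("panel size must be positive")
    n = g.n_covered
    return n, round(100.0 * n / panel_size, 1)


def haploidize(genotypes: np.ndarray, seed: int = 0) -> np.ndarray:
    """Sample one allele per site from diploid dosages (for uniform-ploidy IBS)."""
    rng = np.random.default_rng(seed)
    g = np.asarray(genotypes)
    out = np.where(g == 2, 1, np.where(g == 0, 0, MISSING)).astype(np.int8)
    het = g == 1
    out[het] = rng.integers(0, 2, size=int(het.sum()))
    out[g == MISSING] = MISSING
    return out


def ibs_matrix(calls: np.ndarray, individuals: Sequence[str],
               min_overlap: int = 500) -> IBSMatrix:
    """Pairwise allele-sharing matrix from haploid call vectors.

    ``calls`` is individuals x sites with entries {0, 1, -1 missing};
    p(IBS) for a pair is the fraction of jointly non-missing sites with
    identical alleles. Pairs overlapping fewer than ``min_overlap`` sites are
    flagged; zero-overlap pairs get NaN.
    """
    X = np.asarray(calls)
    n = X.shape[0]
    if n < 2:
        raise ValueError("ibs_matrix needs at least 2 individuals")
    valid = X != MISSING
    p = np.ones((n, n))
    ov = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        vi = valid[i]
        xi = X[i]
        both = valid[i + 1:] & vi
        same = (X[i + 1:] == xi) & both
        o = both.sum(axis=1)
        s = same.sum(axis=1)
        ov[i, i + 1:] = ov[i + 1:, i] = o
        with np.errstate(invalid="ignore"):
            pij = np.where(o > 0, s / np.maximum(o, 1), np.nan)
        p[i, i + 1:] = p[i + 1:, i] = pij
        ov[i, i] = int(vi.sum())
    return IBSMatrix(list(individuals), p, ov, min_overlap)


def classical_mds(d: IBSMatrix | np.ndarray, n_dims: int = 2,
                  individuals: Optional[Sequence[str]] = None):
    """Torgerson double-centering MDS on a distance matrix.

    Returns (coordinates, eigenvalues). Coordinates are eigenvectors scaled
    by sqrt(eigenvalue); each axis is sign-fixed so its first nonzero loading
    is positive.
    """
    if isinstance(d, IBSMatrix):
        individuals = d.individuals
        D = d.distance
        if np.isnan(D).any() or d.flagged.any():
            bad = sorted(set(np.where(np.isnan(D) | d.flagged)[0]))
            raise ValueError(
                f"distance matrix has unreliable pairs; drop individuals {bad} first")
    else:
        D = np.asarray(d, dtype=float)
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(w)[::-1][:n_dims]
    lam = w[order]
    vec = v[:, order]
    coords = vec * np.sqrt(np.clip(lam, 0, None))
    for a in range(coords.shape[1]):
        col = coords[:, a]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, a] = -col
    return coords, lam


def _admix_loglik(G, C, mask, Q, F) -> float:
    P = np.clip(Q @ F, 1e-12, 1 - 1e-12)
    with np.errstate(invalid="ignore"):
        ll = G * np.log(P) + (C - G) * np.log1p(-P)
    return float(ll[mask].sum())


def admixture_fit(G: np.ndarray, ploidy: np.ndarray, K: int, seed: int = 0,
                  tol: float = 1e-6, max_iter: int = 2000,
                  track_loglik: bool = True) -> AdmixtureFit:
    """Unsupervised admixture by binomial-likelihood EM.

    ``G`` is individuals x sites alt-allele counts (missing -1); ``ploidy``
    gives per-individual allele counts c_i (2 diploid, 1 pseudohaploid).
    Model: g_ij ~ Binomial(c_i, p_ij), p_ij = sum_k Q_ik F_kj. The FRAPPE-style
    EM update is used; the log-likelihood is non-decreasing every iteration
    and missing entries contribute nothing. F is clipped to
    [1e-6, 1 - 1e-6] to keep the likelihood finite.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    mask = G != MISSING
    if not mask.any(axis=1).all():
        raise ValueError("admixture_fit: individual with no observed genotypes")
    ploidy = np.asarray(ploidy, dtype=float)
    C = np.broadcast_to(ploidy[:, None], (n, m)).copy()
    Gm = np.where(mask, G, 0.0)
    C = np.where(mask, C, 0.0)
    if K == 1:
        tot = C.sum(axis=0)
        F = np.clip(np.divide(Gm.sum(axis=0), tot, out=np.full(m, 0.5), where=tot > 0),
                    1e-6, 1 - 1e-6)[None, :]
        Q = np.ones((n, 1))
        ll = _admix_loglik(Gm, C, mask, Q, F)
        return AdmixtureFit(1, Q, F, ll, np.array([ll]), seed, True, 0)
    rng = np.random.default_rng(seed)
    # per-row init keyed on the genotype row itself: identical individuals
    # start identically and, by symmetry of the updates, stay identical
    import zlib
    Q = np.vstack([
        np.random.default_rng([seed, zlib.crc32(np.ascontiguousarray(G[i]).tobytes())]
                              ).dirichlet(np.ones(K))
        for i in range(n)])
    F = rng.uniform(0.05, 0.95, size=(K, m))
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P = np.clip(Q @ F, 1e-9, 1 - 1e-9)
        A = Gm / P            # zero where missing since Gm zero
        B = (C - Gm) / (1 - P)
        Ci = C.sum(axis=1)
        Qnew = Q * (A @ F.T + B @ (1 - F).T) / Ci[:, None]
        Qnew /= Qnew.sum(axis=1, keepdims=True)
        num = F * (Q.T @ A)
        den = num + (1 - F) * (Q.T @ B)
        Fnew = np.where(den > 0, num / np.maximum(den, 1e-300), F)
        F = np.clip(Fnew, 1e-6, 1 - 1e-6)
        Q = Qnew
        ll = _admix_loglik(Gm, C, mask, Q, F)
        if track_loglik:
            trace.append(ll)
        if prev > -np.inf and ll - prev < tol * max(1.0, abs(prev)):
            converged = True
            prev = ll
            break
        prev = ll
    if not converged:
        import warnings
        warnings.warn(f"admixture_fit (K={K}, seed={seed}) did not converge "
                      f"in {max_iter} iterations", RuntimeWarning)
    return AdmixtureFit(K, Q, F, prev, np.asarray(trace), seed, converged, it)


def align_components(Q_ref: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Permutation of Q's columns best matching Q_ref (Hungarian on L2 cost)."""
    from scipy.optimize import linear_sum_assignment
    K = Q.shape[1]
    cost = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            cost[a, b] = np.sum((Q_ref[:, a] - Q[:, b]) ** 2)
    _, perm = linear_sum_assignment(cost)
    return perm


def align_modes(fits: Sequence[AdmixtureFit], rmse_threshold: float = 0.05):
    """Select and align the major mode across admixture replicates.

    All replicates are aligned (column-permuted) to the highest-likelihood
    fit; replicates within pairwise aligned-Q RMSE < ``rmse_threshold`` form
    a mode (connected components); the major mode is the largest, ties broken
    by higher mean log-likelihood, and its highest-likelihood member is the
    representative. Returns (representative fit, permutations, mode members).
    """
    if not fits:
        raise ValueError("align_modes needs at least one fit")
    K = fits[0].K
    n = fits[0].Q.shape[0]
    for f in fits:
        if f.K != K or f.Q.shape[0] != n:
            raise ValueError("replicates must share K and individuals")
    ref = max(range(len(fits)), key=lambda i: fits[i].loglik)
    perms = [align_components(fits[ref].Q, f.Q) for f in fits]
    aligned = [f.Q[:, p] for f, p in zip(fits, perms)]
    nrep = len(fits)
    adj = np.zeros((nrep, nrep), dtype=bool)
    for i in range(nrep):
        for j in range(i, nrep):
            rmse = float(np.sqrt(np.mean((aligned[i] - aligned[j]) ** 2)))
            adj[i, j] = adj[j, i] = rmse < rmse_threshold
    # connected components
    comp = np.full(nrep, -1)
    c = 0
    for i in range(nrep):
        if comp[i] >= 0:
            continue
        stack = [i]
        comp[i] = c
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(adj[u]):
                if comp[v] < 0:
                    comp[v] = c
                    stack.append(v)
        c += 1
    sizes = [(int(np.sum(comp == k)),
              float(np.mean([fits[i].loglik for i in np.flatnonzero(comp == k)])))
             for k in range(c)]
    major = max(range(c), key=lambda k: sizes[k])
    members = [int(i) for i in np.flatnonzero(comp == major)]
    rep = max(members, key=lambda i: fits[i].loglik)
    return fits[rep], perms, members
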