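"""Genetic sex and contamination estimation for shotgun ancient DNA.

Sex is called from the fraction of sex-chromosome reads aligning to Y
(Ry = nY / (nX + nY)) with a normal-approximation 95% CI and the published
decision thresholds (XY when the CI lies above 0.075, XX when below 0.016).
Mitochondrial contamination is a two-component per-read mixture likelihood
against the sample's own consensus versus a panel of potential contaminant
haplotypes, maximized on a grid with a profile-likelihood CI. Male
X-chromosome contamination uses a method-of-moments estimator: excess
minor-allele fraction at known polymorphic sites over the mismatch rate at
nearby monomorphic sites, scaled by mean heterozygosity, with a bootstrap CI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .qc import AlignedReadSet


@dataclass
class SexCall:
    nX: int
    nY: int
    ry: float
    ci_low: float
    ci_high: float
    assignment: str   # "XX" | "XY" | "inconclusive"


@dataclass
class ContamEstimate:
    method: str       # "mt_mixture" | "x_moments"
    estimate: float
    ci_low: float
    ci_high: float
    n_informative: int


def ry_sex(nX: int, nY: int, xy_threshold: float = 0.075,
           xx_threshold: float = 0.016) -> SexCall:
    """Sex assignment from X/Y-aligned read counts.

    Ry = nY/(nX+nY) with 95% CI ry ± 1.96 sqrt(ry(1-ry)/n); XY when the
    whole CI sits above ``xy_threshold``, XX when below ``xx_threshold``,
    otherwise inconclusive.
    """
    n = nX + nY
    if n <= 0:
        raise ValueError("ry_sex requires nX + nY > 0")
    ry = nY / n
    half = 1.96 * np.sqrt(ry * (1 - ry) / n)
    lo, hi = max(0.0, ry - half), min(1.0, ry + half)
    if lo > xy_threshold:
        call = "XY"
    elif hi < xx_threshold:
        call = "XX"
    else:
        call = "inconclusive"
    return SexCall(nX, nY, ry, lo, hi, call)


def count_sex_reads(rs: AlignedReadSet, x_contig: str = "chrX",
                    y_contig: str = "chrY") -> tuple[int, int]:
    nX = sum(1 for r in rs.reads if r.contig == x_contig)
    nY = sum(1 for r in rs.reads if r.contig == y_contig)
    return nX, nY


def _mt_pileup(rs: AlignedReadSet, contig: str, end_trim: int,
               min_bq: int = 0) -> dict:
    """pos -> list of bases, after trimming ``end_trim`` bases from each read end."""
    pile: dict = {}
    for r in rs.reads:
        if r.contig != contig:
            continue
        L = len(r.seq)
        for off in range(end_trim, L - end_trim):
            if r.quals[off] < min_bq:
                continue
            pile.setdefault(r.start + off, []).append(r.seq[off])
    return pile


def mt_consensus(rs: AlignedReadSet, contig: str = "chrMT", min_depth: int = 3,
                 end_trim: int = 7) -> str:
    """Majority-rule mtDNA consensus.

    ``end_trim`` bases at both read ends are disregarded (deamination is
    concentrated there); sites with depth < ``min_depth`` or tied majorities
    emit N.
    """
    length = len(rs.reference[contig])
    pile = _mt_pileup(rs, contig, end_trim)
    out = ["N"] * length
    for pos, bases in pile.items():
        if len(bases) < min_depth:
            continue
        vals, counts = np.unique(bases, return_counts=True)
        top = counts.max()
        winners = vals[counts == top]
        if len(winners) == 1:
            out[pos - 1] = str(winners[0])
    return "".join(out)


_TRANSITION = {("C", "T"), ("T", "C"), ("G", "A"), ("A", "G")}


def mt_contamination(rs: AlignedReadSet, consensus: str,
                     contaminant_panel: Sequence[Mapping[int, str] | str],
                     error_rate: Optional[float] = None,
                     contig: str = "chrMT", end_trim: int = 7,
                     grid_step: float = 0.001) -> ContamEstimate:
    """Two-component mixture likelihood for mtDNA contamination.

    Each read's likelihood under a source haplotype is a product of per-base
    terms (1 - eps) for matches and eps/3 for mismatches; the mixture is
    (1-c) L(consensus) + c mean_h L(h). c-hat maximizes the summed log
    likelihood on a grid over [0, 1]; the 95% CI is the profile-likelihood
    set within 1.92 log units of the maximum. ``end_trim`` terminal bases are
    excluded (damage confounding); so are consensus Ns. Panel entries may be
    full sequences or {pos: base} difference maps against the consensus.

    When ``error_rate`` is None it is estimated from the mismatch rate at
    positions where consensus and every panel haplotype agree.
    """
    # materialize panel base accessors
    def panel_base(h, pos):
        if isinstance(h, str):
            return h[pos - 1] if pos <= len(h) else "N"
        return h.get(pos, consensus[pos - 1])

    per_read = []   # (n_match_cons, n_mismatch_cons, per-hap match/mismatch)
    nH = len(contaminant_panel)
    if nH == 0:
        raise ValueError("contaminant panel is empty")
    err_num = err_den = 0
    stats = []
    for r in rs.reads:
        if r.contig != contig:
            continue
        L = len(r.seq)
        mc = xc = 0
        mh = np.zeros(nH, dtype=np.int64)
        xh = np.zeros(nH, dtype=np.int64)
        for off in range(end_trim, L - end_trim):
            pos = r.start + off
            cb = consensus[pos - 1] if pos <= len(consensus) else "N"
            if cb == "N":
                continue
            b = r.seq[off]
            if b not in "ACGT":
                continue
            hb = [panel_base(h, pos) for h in contaminant_panel]
            if all(x == cb for x in hb):
                err_den += 1
                if b != cb:
                    err_num += 1
            if b == cb:
                mc += 1
            else:
                xc += 1
            for k, x in enumerate(hb):
                if b == x:
                    mh[k] += 1
                else:
                    xh[k] += 1
        if mc + xc > 0:
            stats.append((mc, xc, mh, xh))
    if not stats:
        raise ValueError("unidentifiable: no reads overlap usable sites")
    eps = error_rate
    if eps is None:
        eps = max(err_num / err_den if err_den else 0.001, 1e-4)
    la, lb = np.log1p(-eps), np.log(eps / 3.0)
    a = np.array([mc * la + xc * lb for mc, xc, _, _ in stats])
    # log mean likelihood over panel haplotypes
    lh = np.array([mh * la + xh * lb for _, _, mh, xh in stats])  # reads x H
    mx = lh.max(axis=1, keepdims=True)
    b = (mx[:, 0] + np.log(np.exp(lh - mx).mean(axis=1)))
    informative = int(np.sum(np.abs(a - b) > 1e-9))
    if informative == 0:
        raise ValueError("unidentifiable: no read covers a discriminating site")
    m = np.maximum(a, b)
    ea, eb = np.exp(a - m), np.exp(b - m)
    cs = np.arange(0.0, 1.0 + 0.5 * grid_step, grid_step)
    ll = np.array([np.sum(np.log((1 - c) * ea + c * eb + 1e-300)) for c in cs])
    i = int(np.argmax(ll))
    keep = ll >= ll[i] - 1.92
    return ContamEstimate("mt_mixture", float(cs[i]),
                          float(cs[keep].min()), float(cs[keep].max()),
                          informative)


def x_contamination(rs: AlignedReadSet, x_sites: pd.DataFrame,
                    min_mapq: int = 30, min_bq: int = 20,
                    x_contig: str = "chrX", min_sites: int = 50,
                    min_depth: int = 2,
                    n_boot: int = 200, seed: int = 0) -> ContamEstimate:
    """Method-of-moments male X contamination estimate.

    A male carries one X allele, so excess minor-allele reads at known
    polymorphic sites signal contamination (or error). With m_poly the
    pooled minor-allele read fraction at polymorphic sites, m_mono the
    mismatch rate at monomorphic flanking positions (error control), and
    2f(1-f) the chance a contaminant allele differs from the endogenous one:
    c-hat = (m_poly - m_mono) / mean_site[2 f (1 - f)], clamped to [0, 1],
    with a site-bootstrap percentile CI (``n_boot`` resamples).
    ``x_sites`` columns: contig, pos, ref, alt, f.

    Two robustness filters: polymorphic sites enter only at depth >=
    ``min_depth`` (a single read can never expose a minor allele, so
    depth-1 sites would dilute the signal), and C→T / G→A mismatch types are
    excluded from the monomorphic error control because terminal deamination
    would otherwise swamp it (polymorphic sites are transversion-typed, so
    damage products never count as alleles there).
    """
    sites = x_sites[x_sites["contig"] == x_contig]
    if len(sites) == 0:
        raise ValueError("insufficient sites: no polymorphic X sites supplied")
    pos_map = {int(p): j for j, p in enumerate(sites["pos"].to_numpy())}
    refs = sites["ref"].to_numpy()
    alts = sites["alt"].to_numpy()
    fs = sites["f"].to_numpy()
    if np.all((fs <= 0) | (fs >= 1)):
        raise ValueError("unidentifiable: all sites monomorphic")
    ref_seq = rs.reference[x_contig]
    poly_n = np.zeros(len(sites), dtype=np.int64)
    poly_counts: dict = {j: {} for j in range(len(sites))}
    mono_n: dict = {}
    mono_x: dict = {}
    for r in rs.reads:
        if r.contig != x_contig or r.mapq < min_mapq:
            continue
        for off in range(len(r.seq)):
            if r.quals[off] < min_bq:
                continue
            pos = r.start + off
            b = r.seq[off]
            if b not in "ACGT":
                continue
            j = pos_map.get(pos)
            if j is not None:
                if b == refs[j] or b == alts[j]:
                    poly_n[j] += 1
                    poly_counts[j][b] = poly_counts[j].get(b, 0) + 1
            else:
                rb = ref_seq[pos - 1]
                if (rb, b) in (("C", "T"), ("G", "A")):
                    continue  # deamination-like: not usable as error control
                mono_n[pos] = mono_n.get(pos, 0) + 1
                if b != rb:
                    mono_x[pos] = mono_x.get(pos, 0) + 1
    covered = [j for j in range(len(sites)) if poly_n[j] >= min_depth]
    if len(covered) < min_sites:
        raise ValueError(f"insufficient sites: {len(covered)} informative "
                         f"polymorphic sites < {min_sites}")
    poly_minor = np.array(
        [poly_n[j] - max(poly_counts[j].values()) for j in covered], dtype=float)
    poly_tot = poly_n[covered].astype(float)
    het = 2 * fs[covered] * (1 - fs[covered])
    mono_pos = sorted(mono_n)
    mono_tot = np.array([mono_n[p] for p in mono_pos], dtype=float)
    mono_mis = np.array([mono_x.get(p, 0) for p in mono_pos], dtype=float)

    def estimate(idx_p, idx_m):
        mp = poly_minor[idx_p].sum() / max(poly_tot[idx_p].sum(), 1.0)
        mm = (mono_mis[idx_m].sum() / max(mono_tot[idx_m].sum(), 1.0)
              if len(idx_m) else 0.0)
        denom = het[idx_p].mean()
        return float(np.clip((mp - mm) / denom, 0.0, 1.0))

    all_p = np.arange(len(covered))
    all_m = np.arange(len(mono_pos))
    c_hat = estimate(all_p, all_m)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        bp = rng.integers(0, len(all_p), size=len(all_p))
        bm = (rng.integers(0, len(all_m), size=len(all_m))
              if len(all_m) else all_m)
        boots.append(estimate(bp, bm))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ContamEstimate("x_moments", c_hat, float(lo), float(hi),
                          len(covered))
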