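"""Codon-aware diversity, divergence and selection statistics.

Implements Nei-Gojobori synonymous/nonsynonymous counting (unweighted, and
transition/transversion-weighted with bias R), Jukes-Cantor and gamma
distance corrections, Nei's nucleotide diversity partitioned into silent
(synonymous + noncoding) and replacement classes, haplotype diversity,
Tajima's D, between-group divergence (Ka, Ks) and the McDonald-Kreitman
test with a two-tailed Fisher's exact probability.

Conventions: the unweighted scheme is used for diversity/divergence/MK
(as population-genetics packages such as DnaSP do); the weighted scheme is
reserved for phylogenetic synonymous distances.  Gap/ambiguity handling is
complete deletion — any column carrying a non-ACGT character in any
analysed sequence is removed, and codons losing a column are dropped whole.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import _codon
from .core import SiteClassMask
from ._codon import ng_diff_counts, ng_site_counts  # re-exported operations

__all__ = [
    "ng_site_counts", "ng_diff_counts", "jc_correct", "gamma_correct",
    "pi_by_class", "tajimas_d", "haplotype_diversity", "divergence",
    "mk_test", "summarize_diversity",
    "DiversitySummary", "DivergenceSummary", "MKResult", "SaturationError",
]

_ACGT = frozenset("ACGT")


class SaturationError(ValueError):
    """Raised when a proportion of differences is beyond the correctable range."""


def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        raise SaturationError(f"p = {p:.4f} >= 0.75: distance saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def gamma_correct(p: float, a: float = 1.0) -> float:
    """Gamma-rate JC correction d = (3/4) a [(1 - 4p/3)^(-1/a) - 1].

    With shape a = 1 this reduces to d = p / (1 - 4p/3).
    """
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        raise SaturationError(f"p = {p:.4f} >= 0.75: distance saturated")
    if a <= 0:
        raise ValueError("gamma shape must be positive")
    return 0.75 * a * ((1.0 - 4.0 * p / 3.0) ** (-1.0 / a) - 1.0)


# ---------------------------------------------------------------------------
# complete deletion and per-pair class counts

def _complete_deletion(rows: list[str], mask: SiteClassMask):
    """Keep codons and noncoding columns where every row is plain ACGT.

    Returns (codon index matrix [n_seq, n_codon], noncoding character
    matrix [n_seq, n_noncod]).
    """
    kept_codons = []
    for cols in mask.codon_columns:
        # a codon is usable only when every row carries a sense codon there
        # (gaps, ambiguity codes and frame-disrupted stops are all missing data)
        ok = all("".join(r[c] for c in cols) in _codon.CODON_INDEX for r in rows)
        if ok:
            kept_codons.append(cols)
    idx = np.array(
        [[_codon.CODON_INDEX["".join(r[c] for c in cols)] for cols in kept_codons]
         for r in rows],
        dtype=np.int64).reshape(len(rows), len(kept_codons))
    nc_cols = [c for c in mask.noncoding_columns if all(r[c] in _ACGT for r in rows)]
    nc = np.array([[r[c] for c in nc_cols] for r in rows]).reshape(len(rows), len(nc_cols))
    return idx, nc


def _pair_class_counts(idx_a, idx_b, nc_a, nc_b, scheme="unweighted", R=2.0):
    """Per-pair (silent_diffs, silent_sites, nonsyn_diffs, nonsyn_sites)."""
    SD, ND = _codon.diff_arrays()
    S = _codon.syn_sites_array(scheme, R)
    sd = float(SD[idx_a, idx_b].sum())
    nd = float(ND[idx_a, idx_b].sum())
    s_sites = 0.5 * float(S[idx_a].sum() + S[idx_b].sum())
    n_sites = 3.0 * len(idx_a) - s_sites
    nc_diffs = float(np.sum(nc_a != nc_b))
    return sd + nc_diffs, s_sites + nc_a.shape[-1], nd, n_sites


# ---------------------------------------------------------------------------
# summaries

@dataclass
class DiversitySummary:
    n: int
    S: int
    Hd: float | None
    pi_silent: float | None
    pi_nonsyn: float | None
    tajima_D: float | None
    sites_used: dict


@dataclass
class DivergenceSummary:
    Ka: float | None
    Ks: float | None
    Ka_over_Ks: float | None
    group_labels: tuple[str, str]
    sites_used: dict
    n_pairs: int
    n_saturated: int = 0


@dataclass
class MKResult:
    Pn: int
    Ps: int
    Dn: int
    Ds: int
    fisher_p: float | None
    NI: float | None


def pi_by_class(rows: list[str], mask: SiteClassMask,
                scheme: str = "unweighted", R: float = 2.0,
                correct_mean: bool = False):
    """Nei's pi at silent (synonymous + noncoding) and nonsynonymous positions.

    Per pair the proportion of differences is Jukes-Cantor corrected, then
    averaged over all pairs (``correct_mean=True`` instead corrects the
    averaged proportion).  Returns (pi_silent, pi_nonsyn); either is None
    when its site class has no usable sites.
    """
    if len(rows) < 2:
        raise ValueError("need >= 2 sequences")
    idx, nc = _complete_deletion(rows, mask)
    n = len(rows)
    ps_list, pn_list = [], []
    for i in range(n):
        for j in range(i + 1, n):
            sd, ss, nd, ns = _pair_class_counts(idx[i], idx[j], nc[i], nc[j], scheme, R)
            ps_list.append((sd, ss))
            pn_list.append((nd, ns))

    def summarize(pairs):
        if not pairs or pairs[0][1] <= 0:
            return None
        if correct_mean:
            p = float(np.mean([d / s for d, s in pairs]))
            return jc_correct(p)
        return float(np.mean([jc_correct(d / s) for d, s in pairs]))

    return summarize(ps_list), summarize(pn_list)


def haplotype_diversity(counts) -> float:
    """Nei's haplotype diversity Hd = n/(n-1) (1 - sum (c_i/n)^2)."""
    counts = np.asarray(list(counts), dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least 2 sampled sequences")
    freqs = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(freqs ** 2)))


def _usable_columns(rows: list[str], mask: SiteClassMask) -> np.ndarray:
    """Character matrix over all non-excluded columns passing complete deletion."""
    cols = sorted({c for cols in mask.codon_columns for c in cols}
                  | set(int(c) for c in mask.noncoding_columns))
    cols = [c for c in cols if all(r[c] in _ACGT for r in rows)]
    return np.array([[r[c] for c in cols] for r in rows]).reshape(len(rows), len(cols))


def tajimas_d(rows: list[str], mask: SiteClassMask) -> float | None:
    """Tajima's (1989) D over all usable sites; None when S == 0."""
    n = len(rows)
    if n < 4:
        raise ValueError("need n >= 4 sequences")
    m = _usable_columns(rows, mask)
    seg = np.array([len(set(m[:, c])) > 1 for c in range(m.shape[1])])
    S = int(seg.sum())
    if S == 0:
        return None
    k = float(np.mean([
        np.sum(m[i] != m[j]) for i in range(n) for j in range(i + 1, n)]))
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    return (k - S / a1) / math.sqrt(var)


def summarize_diversity(rows: list[str], mask: SiteClassMask,
                        labels: list[str] | None = None) -> DiversitySummary:
    """n, S, Hd, pi_silent, pi_nonsyn and Tajima's D for one group."""
    n = len(rows)
    m = _usable_columns(rows, mask)
    S = int(sum(len(set(m[:, c])) > 1 for c in range(m.shape[1])))
    hap_counts: dict[str, int] = {}
    for i in range(n):
        key = "".join(m[i])
        hap_counts[key] = hap_counts.get(key, 0) + 1
    hd = haplotype_diversity(hap_counts.values()) if n >= 2 else None
    pi_s, pi_n = pi_by_class(rows, mask) if n >= 2 else (None, None)
    D = tajimas_d(rows, mask) if (n >= 4 and S > 0) else None
    idx, nc = _complete_deletion(rows, mask)
    Ssites = _codon.syn_sites_array("unweighted")
    sites = {
        "silent_sites": float(np.mean(Ssites[idx].sum(axis=1))) + nc.shape[1]
        if idx.size else float(nc.shape[1]),
        "nonsyn_sites": 3.0 * idx.shape[1] - float(np.mean(Ssites[idx].sum(axis=1)))
        if idx.size else 0.0,
        "noncoding_sites": int(nc.shape[1]),
        "codons": idx.shape[1],
    }
    return DiversitySummary(n=n, S=S, Hd=hd, pi_silent=pi_s, pi_nonsyn=pi_n,
                            tajima_D=D, sites_used=sites)


def divergence(rows_a: list[str], rows_b: list[str], mask: SiteClassMask,
               labels: tuple[str, str] = ("A", "B"),
               scheme: str = "unweighted", R: float = 2.0) -> DivergenceSummary:
    """Mean JC-corrected per-class divergence over all between-group pairs.

    Saturated pairs (p >= 0.75 in either class) are excluded from the mean
    with a warning.
    """
    if not rows_a or not rows_b:
        raise ValueError("both groups must be non-empty")
    idx, nc = _complete_deletion(rows_a + rows_b, mask)
    na = len(rows_a)
    ka_list, ks_list = [], []
    n_sat = 0
    ss_used = ns_used = 0.0
    for i in range(na):
        for j in range(na, na + len(rows_b)):
            sd, ss, nd, ns = _pair_class_counts(idx[i], idx[j], nc[i], nc[j], scheme, R)
            try:
                ks = jc_correct(sd / ss) if ss > 0 else None
                ka = jc_correct(nd / ns) if ns > 0 else None
            except SaturationError:
                n_sat += 1
                continue
            ks_list.append(ks)
            ka_list.append(ka)
            ss_used, ns_used = ss, ns
    if n_sat:
        warnings.warn(f"{n_sat} saturated pair(s) excluded from divergence mean")
    ks = float(np.mean([v for v in ks_list if v is not None])) if any(
        v is not None for v in ks_list) else None
    ka = float(np.mean([v for v in ka_list if v is not None])) if any(
        v is not None for v in ka_list) else None
    ratio = (ka / ks) if (ka is not None and ks is not None and ks > 0) else None
    return DivergenceSummary(Ka=ka, Ks=ks, Ka_over_Ks=ratio, group_labels=labels,
                             sites_used={"silent_sites": ss_used, "nonsyn_sites": ns_used},
                             n_pairs=len(ks_list), n_saturated=n_sat)


def _consensus_codon(col_idx: np.ndarray) -> int:
    vals, counts = np.unique(col_idx, return_counts=True)
    return int(vals[np.argmax(counts)])


def mk_test(rows_in: list[str], rows_out: list[str], mask: SiteClassMask) -> MKResult:
    """McDonald-Kreitman 2x2 contrast of silent vs replacement changes.

    Polymorphic cells count segregating changes within the ingroup; fixed
    cells count positions monomorphic in both groups with different states
    (a position both segregating and divergent counts once, as polymorphic).
    Coding changes are classed by pathway-averaged codon counting, with each
    cell rounded to the nearest integer at the end.  Significance is the
    two-tailed Fisher's exact probability; NI = (Pn/Ps)/(Dn/Ds).
    """
    if len(rows_in) < 2:
        raise ValueError("ingroup needs >= 2 sequences")
    if len(rows_out) < 1:
        raise ValueError("outgroup needs >= 1 sequence")
    rows = rows_in + rows_out
    idx, nc = _complete_deletion(rows, mask)
    nin = len(rows_in)
    SENSE = _codon.SENSE_CODONS
    pn = ps = dn = ds = 0.0

    for c in range(idx.shape[1]):
        col_in = idx[:nin, c]
        col_out = idx[nin:, c]
        in_codons = [SENSE[k] for k in col_in]
        out_codons = [SENSE[k] for k in col_out]
        cons = SENSE[_consensus_codon(col_in)]
        # ingroup polymorphism: each distinct non-consensus codon, counted
        # against the ingroup consensus
        seg_positions = {j for cd in in_codons for j in range(3) if cd[j] != cons[j]}
        for cd in sorted(set(in_codons) - {cons}):
            s, n = ng_diff_counts(cons, cd)
            ps += s
            pn += n
        # fixed differences: positions monomorphic in both groups, different,
        # and not segregating in the ingroup
        fixed = []
        for j in range(3):
            in_states = {cd[j] for cd in in_codons}
            out_states = {cd[j] for cd in out_codons}
            if (len(in_states) == 1 and len(out_states) == 1
                    and in_states != out_states and j not in seg_positions):
                fixed.append(j)
        if fixed:
            derived = list(cons)
            for j in fixed:
                derived[j] = out_codons[0][j]
            derived = "".join(derived)
            if derived in _codon.AA:
                s, n = ng_diff_counts(cons, derived)
            else:  # fixed path ends in a stop codon: count as replacement
                s, n = 0.0, float(len(fixed))
            ds += s
            dn += n

    for c in range(nc.shape[1]):
        col_in = set(nc[:nin, c])
        col_out = set(nc[nin:, c])
        if len(col_in) > 1:
            ps += len(col_in) - 1
        elif len(col_out) == 1 and col_in != col_out:
            ds += 1

    Pn, Ps, Dn, Ds = (int(round(v)) for v in (pn, ps, dn, ds))
    return mk_table_stats(Pn, Ps, Dn, Ds)


def mk_table_stats(Pn: int, Ps: int, Dn: int, Ds: int) -> MKResult:
    """Fisher's exact two-tailed probability and NI for an MK 2x2 table."""
    total = Pn + Ps + Dn + Ds
    if total == 0 or (Pn + Ps == 0) or (Dn + Ds == 0) or (Pn + Dn == 0) or (Ps + Ds == 0):
        p = None
    else:
        _, p = stats.fisher_exact([[Pn, Ps], [Dn, Ds]], alternative="two-sided")
        p = float(p)
    ni = (Pn * Ds) / (Ps * Dn) if (Ps > 0 and Dn > 0) else None
    return MKResult(Pn=Pn, Ps=Ps, Dn=Dn, Ds=Ds, fisher_p=p, NI=ni)
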