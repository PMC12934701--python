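"""The 17 unphased selective-sweep summary statistics.

All statistics operate on a :class:`GenotypeWindow`: the (up to) 128 variants
closest to the sweep site, as an ``n x S`` matrix of alternate-allele dosages
(0/1/2) over ``n`` diploid individuals, with base positions.  Phase is never
used: haplotype-style quantities are computed on multilocus genotype rows
("diplotypes") and on genotype dosage correlations.

The statistics are

* site-frequency spectrum: number of segregating sites S, nucleotide
  diversity pi (window total of per-site unbiased heterozygosity), Watterson's
  theta (window total), Tajima's D, and the variance of Tajima's D over
  non-overlapping 16-variant sub-windows;
* diplotype frequencies: number of distinct diplotypes and the unphased
  homozygosity statistics h1, h2, h12, h123, h2/h1 (genotype analogues of
  Garud's haplotype H statistics);
* genotype mismatch ("gkl") distribution: variance, skew and excess kurtosis
  of the pairwise count of sites at which two individuals' dosages differ;
* linkage disequilibrium: mean Rogers-Huff genotypic r^2 over SNP pairs, and
  Kim's omega contrasting within-block against between-block r^2 over the
  best split of the window;
* an unphased H-scan: the mean base-pair length of pairwise diplotype
  identity tracts through the window center, normalized by the window span
  so it lies in [0, 1].

A window is *valid* only if every one of the 17 values is finite.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
import numpy as np
from scipy import stats as sps

__all__ = [
    "GenotypeWindow",
    "StatVector",
    "STAT_NAMES",
    "extract_window",
    "window_from_result",
    "sfs_stats",
    "diplotype_stats",
    "gkl_stats",
    "ld_stats",
    "hscan_stat",
    "compute_all",
]

STAT_NAMES = [
    "S", "pi", "thetaW", "D", "varD",
    "n_diplo", "h1", "h2", "h12", "h123", "h2h1",
    "gkl_var", "gkl_skew", "gkl_kurt",
    "r2_mean", "omega", "hscan",
]

_VARD_BLOCK = 16  # variants per non-overlapping sub-window for Var[D]


@dataclass
class GenotypeWindow:
    """Dosage matrix of the <=128 variants nearest the sweep site."""

    dosages: np.ndarray  # (n, S) values in {0, 1, 2}
    positions: np.ndarray  # (S,) strictly increasing base coordinates
    center: float

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def S(self) -> int:
        return self.dosages.shape[1]

    @property
    def window_span(self) -> float:
        if self.S < 2:
            return 0.0
        return float(self.positions[-1] - self.positions[0])


@dataclass
class StatVector:
    S: float
    pi: float
    thetaW: float
    D: float
    varD: float
    n_diplo: float
    h1: float
    h2: float
    h12: float
    h123: float
    h2h1: float
    gkl_var: float
    gkl_skew: float
    gkl_kurt: float
    r2_mean: float
    omega: float
    hscan: float
    valid: bool = True

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        return d

    def values(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STAT_NAMES], dtype=float)


def extract_window(
    dosages: np.ndarray,
    positions: np.ndarray,
    center: float,
    max_snps: int = 128,
) -> GenotypeWindow:
    """Keep the ``max_snps`` variants with smallest distance to *center*
    (ties broken toward the lower coordinate), re-sorted by position."""
    positions = np.asarray(positions, dtype=float)
    if dosages.shape[1] != positions.shape[0]:
        raise ValueError("dosages and positions disagree on variant count")
    S = positions.shape[0]
    if S > max_snps:
        dist = np.abs(positions - center)
        order = np.lexsort((positions, dist))[:max_snps]
        keep = np.sort(order)
        dosages = dosages[:, keep]
        positions = positions[keep]
    return GenotypeWindow(
        dosages=np.ascontiguousarray(dosages), positions=positions, center=center
    )


def window_from_result(result, max_snps: int = 128) -> GenotypeWindow:
    """Window around the sweep site (L/2) of a completed SweepResult."""
    if result.status != "complete":
        raise ValueError("abandoned simulations carry no genotypes")
    return extract_window(
        result.dosages, result.positions, result.params.L / 2.0, max_snps
    )


# ---------------------------------------------------------------------------
# site-frequency statistics
# ---------------------------------------------------------------------------


def _tajima_constants(n_chr: int) -> tuple[float, float, float, float]:
    i = np.arange(1, n_chr)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n_chr + 1) / (3.0 * (n_chr - 1))
    b2 = 2.0 * (n_chr**2 + n_chr + 3) / (9.0 * n_chr * (n_chr - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n_chr + 2) / (a1 * n_chr) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, a2, e1, e2


def _pi_total(counts: np.ndarray, n_chr: int) -> float:
    """Sum over sites of unbiased per-site heterozygosity
    2 j (2n - j) / (2n (2n - 1))."""
    j = counts.astype(float)
    return float(np.sum(2.0 * j * (n_chr - j) / (n_chr * (n_chr - 1))))


def _tajima_d(pi: float, S: int, n_chr: int) -> float:
    if S == 0:
        return np.nan
    a1, _, e1, e2 = _tajima_constants(n_chr)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return np.nan
    return (pi - S / a1) / np.sqrt(var)


def sfs_stats(win: GenotypeWindow) -> dict:
    """S, window pi, Watterson's theta, Tajima's D, and Var[D] over
    non-overlapping 16-variant sub-windows (complete blocks only)."""
    n_chr = 2 * win.n
    S = win.S
    counts = win.dosages.sum(axis=0).astype(np.int64)
    pi = _pi_total(counts, n_chr) if S else 0.0
    a1, _, _, _ = _tajima_constants(n_chr)
    thetaW = S / a1 if S else 0.0
    D = _tajima_d(pi, S, n_chr)

    n_blocks = S // _VARD_BLOCK
    if n_blocks >= 2:
        ds = []
        for b in range(n_blocks):
            sl = slice(b * _VARD_BLOCK, (b + 1) * _VARD_BLOCK)
            ds.append(_tajima_d(_pi_total(counts[sl], n_chr), _VARD_BLOCK, n_chr))
        ds = np.array(ds)
        varD = float(np.var(ds, ddof=1)) if np.all(np.isfinite(ds)) else np.nan
    else:
        varD = np.nan
    return {"S": float(S), "pi": pi, "thetaW": thetaW, "D": D, "varD": varD}


# ---------------------------------------------------------------------------
# diplotype frequency statistics
# ---------------------------------------------------------------------------


def diplotype_stats(win: GenotypeWindow) -> dict:
    """Homozygosity statistics on sorted multilocus-genotype frequencies."""
    n = win.n
    _, counts = np.unique(win.dosages, axis=0, return_counts=True)
    p = np.sort(counts / n)[::-1]
    p_pad = np.concatenate([p, np.zeros(3)])  # missing ranks count as 0
    h1 = float(np.sum(p**2))
    h2 = h1 - float(p_pad[0] ** 2)
    h12 = float((p_pad[0] + p_pad[1]) ** 2 + np.sum(p_pad[2:] ** 2))
    h123 = float((p_pad[0] + p_pad[1] + p_pad[2]) ** 2 + np.sum(p_pad[3:] ** 2))
    h2h1 = h2 / h1
    return {
        "n_diplo": float(len(counts)), "h1": h1, "h2": h2,
        "h12": h12, "h123": h123, "h2h1": h2h1,
    }


# ---------------------------------------------------------------------------
# genotype mismatch (gkl) statistics
# ---------------------------------------------------------------------------


def _pairwise_mismatches(dosages: np.ndarray) -> np.ndarray:
    """Number of window sites at which each pair of individuals differ."""
    n, S = dosages.shape
    equal = np.zeros((n, n))
    for k in (0, 1, 2):
        ind = (dosages == k).astype(np.float32)
        equal += ind @ ind.T
    mism = S - equal
    iu = np.triu_indices(n, k=1)
    return np.asarray(mism[iu])


def gkl_stats(win: GenotypeWindow) -> dict:
    """Sample variance, skewness, and excess kurtosis of the pairwise
    genotype-mismatch distribution (bias-corrected sample moments)."""
    m = _pairwise_mismatches(win.dosages)
    var = float(np.var(m, ddof=1))
    if var == 0.0:
        return {"gkl_var": 0.0, "gkl_skew": np.nan, "gkl_kurt": np.nan}
    skew = float(sps.skew(m, bias=False))
    kurt = float(sps.kurtosis(m, fisher=True, bias=False))
    return {"gkl_var": var, "gkl_skew": skew, "gkl_kurt": kurt}


# ---------------------------------------------------------------------------
# linkage disequilibrium statistics
# ---------------------------------------------------------------------------


def _r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """Rogers-Huff genotypic r^2 between SNP pairs (squared Pearson
    correlation of dosage vectors); NaN where a site has zero variance."""
    d = dosages.astype(float)
    sd = d.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(d, rowvar=False)
    c[:, sd == 0] = np.nan
    c[sd == 0, :] = np.nan
    r2 = c**2
    np.fill_diagonal(r2, np.nan)
    return r2


def ld_stats(win: GenotypeWindow, min_omega_snps: int = 6) -> dict:
    """Mean pairwise r^2 and Kim's omega.

    omega maximizes, over split indices l in [2, S-2], the ratio of mean
    within-block r^2 (left block = first l SNPs) to mean between-block r^2.
    Pairs involving a zero-variance site are excluded from both means.
    """
    S = win.S
    if S < 2:
        return {"r2_mean": np.nan, "omega": np.nan}
    r2 = _r2_matrix(win.dosages)
    iu = np.triu_indices(S, k=1)
    vals = r2[iu]
    finite = np.isfinite(vals)
    r2_mean = float(np.mean(vals[finite])) if finite.any() else np.nan

    if S < min_omega_snps:
        return {"r2_mean": r2_mean, "omega": np.nan}

    valid = np.isfinite(r2)
    r2z = np.where(valid, r2, 0.0)
    best = np.nan
    for l in range(2, S - 1):
        left = np.triu(r2z[:l, :l], k=1)
        right = np.triu(r2z[l:, l:], k=1)
        nl = np.triu(valid[:l, :l], k=1).sum()
        nr = np.triu(valid[l:, l:], k=1).sum()
        nb = valid[:l, l:].sum()
        sb = r2z[:l, l:].sum()
        if nl + nr == 0 or nb == 0 or sb == 0:
            continue
        ratio = ((left.sum() + right.sum()) / (nl + nr)) / (sb / nb)
        if not np.isfinite(best) or ratio > best:
            best = ratio
    return {"r2_mean": r2_mean, "omega": best}


# ---------------------------------------------------------------------------
# unphased H-scan
# ---------------------------------------------------------------------------


def hscan_stat(win: GenotypeWindow) -> float:
    """Mean pairwise diplotype-identity tract length through the window
    center, divided by the window span (so the value lies in [0, 1]).

    For each pair of individuals the tract is the maximal contiguous run of
    window variants at which their dosages agree, anchored at the variant(s)
    flanking the center; its length is the base distance between the run's
    outermost variants (0 if the pair disagrees at both flanking variants).
    """
    S = win.S
    if S < 2 or win.window_span <= 0:
        return np.nan
    pos = win.positions
    d = win.dosages
    n = win.n
    kR = int(np.searchsorted(pos, win.center))
    kL = kR - 1
    have_L = kL >= 0
    have_R = kR <= S - 1

    iu = np.triu_indices(n, k=1)
    agree = d[iu[0]] == d[iu[1]]  # (n_pairs, S)
    disagree = ~agree
    P = agree.shape[0]
    tract = np.zeros(P)

    if have_L:
        sub = disagree[:, : kL + 1][:, ::-1]
        any_dis = sub.any(axis=1)
        last_dis = np.where(any_dis, kL - sub.argmax(axis=1), -1)
        left_start = last_dis + 1  # first index of the run ending at kL
        agree_L = agree[:, kL]
    if have_R:
        sub = disagree[:, kR:]
        any_dis = sub.any(axis=1)
        first_dis = np.where(any_dis, kR + sub.argmax(axis=1), S)
        right_end = first_dis - 1  # last index of the run starting at kR
        agree_R = agree[:, kR]

    if have_L and have_R:
        both = agree_L & agree_R
        onlyL = agree_L & ~agree_R
        onlyR = agree_R & ~agree_L
        tract[both] = pos[right_end[both]] - pos[left_start[both]]
        tract[onlyL] = pos[kL] - pos[left_start[onlyL]]
        tract[onlyR] = pos[right_end[onlyR]] - pos[kR]
    elif have_L:
        tract[agree_L] = pos[kL] - pos[left_start[agree_L]]
    else:
        tract[agree_R] = pos[right_end[agree_R]] - pos[kR]

    return float(tract.mean() / win.window_span)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def compute_all(win: GenotypeWindow) -> StatVector:
    """All 17 statistics; ``valid`` is False iff any value is not finite."""
    out = {}
    out.update(sfs_stats(win))
    if win.S > 0 and win.n > 0:
        out.update(diplotype_stats(win))
    else:
        out.update({k: np.nan for k in
                    ("n_diplo", "h1", "h2", "h12", "h123", "h2h1")})
    if win.n >= 3 and win.S > 0:
        out.update(gkl_stats(win))
    else:
        out.update({"gkl_var": np.nan, "gkl_skew": np.nan, "gkl_kurt": np.nan})
    out.update(ld_stats(win))
    out["hscan"] = hscan_stat(win)
    vec = StatVector(**out)
    vec.valid = bool(np.all(np.isfinite(vec.values())))
    return vec
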