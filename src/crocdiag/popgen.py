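"""GenAlEx-style diversity statistics, F-statistics, relatedness, HWE,
Welch contrasts and distance-based two-level AMOVA.

All statistics are computed from called genotypes only.  Expected
heterozygosity uses the plain 1 − Σp² form (no small-sample correction) to
match the conventions of spreadsheet-era population-genetics tools; an
unbiased variant is available by flag.  The fixation index F = (He − Ho)/He
is undefined at monomorphic loci and excluded from means with a reported
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dart_io import MISSING, GenotypeMatrix
from .panel import DistanceMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-locus building blocks
# ---------------------------------------------------------------------------

def _alt_freq(calls: np.ndarray) -> float:
    """Alternate-allele frequency among called genotypes (NaN if none called)."""
    called = calls[calls != MISSING]
    if called.size == 0:
        return np.nan
    return float(called.sum()) / (2 * called.size)


def _locus_stats(calls: np.ndarray, unbiased_he: bool = False) -> dict:
    called = calls[calls != MISSING]
    n = called.size
    if n == 0:
        return dict(n=0, p=np.nan, Na=0.0, Ne=0.0, I=0.0, Ho=0.0, He=0.0, F=np.nan)
    p = float(called.sum()) / (2 * n)
    q = 1 - p
    freqs = np.array([q, p])
    na = float((freqs > 0).sum())
    sum_p2 = float(np.sum(freqs**2))
    ne = 1.0 / sum_p2
    nz = freqs[freqs > 0]
    shannon = float(-(nz * np.log(nz)).sum())
    ho = float((called == 1).mean())
    he = 1.0 - sum_p2
    if unbiased_he:
        he *= 2 * n / (2 * n - 1) if n > 0.5 else 1.0
    f = (he - ho) / he if he > 0 else np.nan
    return dict(n=n, p=p, Na=na, Ne=ne, I=shannon, Ho=ho, He=he, F=f)


@dataclass
class DiversitySummary:
    per_locus: pd.DataFrame   # rows (population, locus_id)
    summary: pd.DataFrame     # Mean/SE per population, Table-2 style columns
    n_f_undefined: dict[str, int]
    locus_inclusion: str

    def to_csv(self, per_locus_path=None, summary_path=None) -> None:
        if per_locus_path is not None:
            self.per_locus.reset_index().to_csv(per_locus_path, index=False)
        if summary_path is not None:
            self.summary.to_csv(summary_path)


def diversity_table(
    m: GenotypeMatrix,
    pops: Mapping[str, Sequence[str]] | None = None,
    locus_inclusion: str = "called",
    unbiased_he: bool = False,
) -> DiversitySummary:
    """Per-population × locus diversity statistics with Mean/SE summaries.

    ``pops`` maps population name → sample ids; by default the sample
    metadata's ``population`` column is used (CANDIDATE excluded).
    ``locus_inclusion`` resolves the convention for loci with no calls in a
    population: ``"called"`` drops them from that population's averages;
    ``"all"`` keeps them as zero-allele rows (Na = Ne = I = Ho = He = 0),
    which deflates Na/Ne means the way some published tables do.
    """
    if locus_inclusion not in ("called", "all"):
        raise ValueError("locus_inclusion must be 'called' or 'all'")
    if pops is None:
        groups = m.samples.groupby("population").groups
        pops = {str(k): list(v) for k, v in groups.items() if k != "CANDIDATE"}
    if not pops:
        raise ValueError("no populations to summarise")

    frames = []
    n_f_undef: dict[str, int] = {}
    summary_rows = []
    for pop, ids in pops.items():
        ids = list(ids)
        if len(ids) == 0:
            raise ValueError(f"population {pop!r} is empty")
        cols = np.asarray([m.sample_ids.get_loc(s) for s in ids])
        recs = []
        for i, locus in enumerate(m.locus_ids):
            st = _locus_stats(m.calls[i, cols], unbiased_he=unbiased_he)
            st["locus_id"] = locus
            recs.append(st)
        df = pd.DataFrame(recs).set_index("locus_id")
        if locus_inclusion == "called":
            df = df[df["n"] > 0]
        df.insert(0, "population", pop)
        frames.append(df)
        n_f_undef[pop] = int(df["F"].isna().sum())

        mean = df[["Na", "Ne", "I", "Ho", "He", "F"]].mean()
        se = df[["Na", "Ne", "I", "Ho", "He", "F"]].std(ddof=1) / np.sqrt(len(df))
        pic = df["He"].mean()  # biallelic PIC (1 − Σp²) coincides with He
        summary_rows.append(
            {"population": pop, "stat": "Mean", "N": len(ids), "Na": mean["Na"],
             "Ne": mean["Ne"], "I": mean["I"], "Ho": mean["Ho"], "He": mean["He"],
             "PIC": pic, "F": mean["F"]})
        summary_rows.append(
            {"population": pop, "stat": "SE", "N": 0, "Na": se["Na"], "Ne": se["Ne"],
             "I": se["I"], "Ho": se["Ho"], "He": se["He"],
             "PIC": df["He"].std(ddof=1) / np.sqrt(len(df)), "F": se["F"]})

    per_locus = pd.concat(frames).set_index("population", append=True).reorder_levels(
        ["population", "locus_id"])
    summary = pd.DataFrame(summary_rows).set_index(["population", "stat"])
    return DiversitySummary(per_locus=per_locus, summary=summary,
                            n_f_undefined=n_f_undef, locus_inclusion=locus_inclusion)


# ---------------------------------------------------------------------------
# F-statistics
# ---------------------------------------------------------------------------

@dataclass
class FStatistics:
    fst_overall: float
    fst_pairwise: pd.DataFrame
    p_pairwise: pd.DataFrame
    fis_per_pop: pd.Series
    fis_overall: float
    n_permutations: int


def _pop_freq_matrix(calls: np.ndarray, pop_cols: dict[str, np.ndarray]):
    """Alt-allele frequency and Ho per population per locus (NaN where uncalled)."""
    freqs, hos = {}, {}
    for pop, cols in pop_cols.items():
        sub = calls[:, cols]
        called = sub != MISSING
        n_called = called.sum(axis=1)
        alt = np.where(called, sub, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[pop] = np.where(n_called > 0, alt / (2 * np.maximum(n_called, 1)),
                                  np.nan)
            hos[pop] = np.where(
                n_called > 0,
                np.where(called, sub == 1, False).sum(axis=1) / np.maximum(n_called, 1),
                np.nan)
    return freqs, hos


def _fst_from_freqs(freq_rows: np.ndarray) -> float:
    """Ratio-of-sums FST = (ΣHT − ΣHS)/ΣHT from a pops × loci frequency array.

    Loci with any population uncalled (NaN) are dropped; HT uses the
    unweighted mean of population frequencies.
    """
    ok = ~np.isnan(freq_rows).any(axis=0)
    f = freq_rows[:, ok]
    if f.size == 0:
        return np.nan
    hs = (2 * f * (1 - f)).mean(axis=0)
    pbar = f.mean(axis=0)
    ht = 2 * pbar * (1 - pbar)
    sum_ht = ht.sum()
    if sum_ht == 0:
        return np.nan
    return float((sum_ht - hs.sum()) / sum_ht)


def f_statistics(
    m: GenotypeMatrix,
    pops: Mapping[str, Sequence[str]] | None = None,
    n_permutations: int = 999,
    seed: int | None = None,
) -> FStatistics:
    """FIS per population and overall, FST overall and pairwise with
    permutation p-values (individuals shuffled across populations)."""
    if pops is None:
        groups = m.samples.groupby("population").groups
        pops = {str(k): list(v) for k, v in groups.items() if k != "CANDIDATE"}
    names = list(pops)
    if len(names) < 2:
        raise ValueError("at least two populations are required")
    pop_cols = {p: np.asarray([m.sample_ids.get_loc(s) for s in pops[p]])
                for p in names}
    freqs, hos = _pop_freq_matrix(m.calls, pop_cols)
    freq_arr = np.vstack([freqs[p] for p in names])

    fst_overall = _fst_from_freqs(freq_arr)
    if np.isnan(fst_overall):
        logger.warning("f_statistics: overall FST undefined (globally monomorphic)")

    # FIS = 1 − mean Ho / mean He within each population (ratio of means)
    fis = {}
    for p in names:
        he = 2 * freqs[p] * (1 - freqs[p])
        ok = ~np.isnan(he)
        denom = np.nansum(he[ok])
        fis[p] = 1 - np.nansum(hos[p][ok]) / denom if denom > 0 else np.nan
    he_all = 2 * freq_arr * (1 - freq_arr)
    denom = np.nansum(he_all)
    ho_all = np.vstack([hos[p] for p in names])
    fis_overall = 1 - np.nansum(ho_all) / denom if denom > 0 else np.nan

    rng = np.random.default_rng(seed)
    fst_pw = pd.DataFrame(np.nan, index=names, columns=names)
    p_pw = pd.DataFrame(np.nan, index=names, columns=names)
    for ai in range(len(names)):
        for bi in range(ai + 1, len(names)):
            a, b = names[ai], names[bi]
            obs = _fst_from_freqs(np.vstack([freqs[a], freqs[b]]))
            fst_pw.loc[a, b] = fst_pw.loc[b, a] = obs
            if np.isnan(obs) or n_permutations == 0:
                continue
            cols = np.concatenate([pop_cols[a], pop_cols[b]])
            na = len(pop_cols[a])
            calls = m.calls[:, cols]
            count = 0
            for _ in range(n_permutations):
                perm = rng.permutation(len(cols))
                pc = {"x": perm[:na], "y": perm[na:]}
                pf, _ = _pop_freq_matrix(calls, pc)
                perm_fst = _fst_from_freqs(np.vstack([pf["x"], pf["y"]]))
                if not np.isnan(perm_fst) and perm_fst >= obs - 1e-12:
                    count += 1
            pval = (count + 1) / (n_permutations + 1)
            p_pw.loc[a, b] = p_pw.loc[b, a] = pval
    np.fill_diagonal(fst_pw.values, 0.0)
    return FStatistics(
        fst_overall=fst_overall, fst_pairwise=fst_pw, p_pairwise=p_pw,
        fis_per_pop=pd.Series(fis), fis_overall=fis_overall,
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# Queller–Goodnight relatedness
# ---------------------------------------------------------------------------

def _qg_directional(gx: np.ndarray, gy: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    """Summed numerator and denominator of the Queller–Goodnight estimator
    with x as reference, over loci (biallelic, alt-allele dosage coding).

    Heterozygous reference loci contribute 0/0 and drop out; loci with
    monomorphic reference frequency (p ∈ {0,1} or NaN) are skipped.
    """
    q = 1 - p
    ok = ~np.isnan(p) & (p > 0) & (p < 1) & (gx != MISSING) & (gy != MISSING)
    num = np.zeros(len(p))
    den = np.zeros(len(p))
    hom_ref = ok & (gx == 0)
    hom_alt = ok & (gx == 2)
    num[hom_ref] = (2 - gy[hom_ref]) - 2 * q[hom_ref]
    den[hom_ref] = 2 * p[hom_ref]
    num[hom_alt] = gy[hom_alt] - 2 * p[hom_alt]
    den[hom_alt] = 2 * q[hom_alt]
    return float(num.sum()), float(den.sum())


def relatedness_qg(
    m: GenotypeMatrix, sample_ids: Sequence[str] | None = None
) -> tuple[pd.DataFrame, float]:
    """Pairwise Queller–Goodnight relatedness within one population.

    Reference allele frequencies for each dyad are estimated from the
    population *excluding the dyad*.  The two directional values are
    averaged; the matrix and the mean over dyads are returned.
    """
    ids = list(m.sample_ids if sample_ids is None else sample_ids)
    if len(ids) < 3:
        raise ValueError("relatedness needs at least 3 individuals")
    cols = np.asarray([m.sample_ids.get_loc(s) for s in ids])
    g = m.calls[:, cols].astype(float)
    g[g == MISSING] = np.nan
    called = ~np.isnan(g)
    tot_alt = np.nansum(g, axis=1)
    tot_n = called.sum(axis=1)

    n = len(ids)
    r = np.full((n, n), np.nan)
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            pair_called = called[:, i].astype(int) + called[:, j].astype(int)
            pair_alt = np.nan_to_num(g[:, i]) + np.nan_to_num(g[:, j])
            n_ref = tot_n - pair_called
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(n_ref > 0, (tot_alt - pair_alt) / (2 * np.maximum(n_ref, 1)),
                             np.nan)
            gi = np.where(called[:, i], g[:, i], MISSING).astype(np.int8)
            gj = np.where(called[:, j], g[:, j], MISSING).astype(np.int8)
            n1, d1 = _qg_directional(gi, gj, p)
            n2, d2 = _qg_directional(gj, gi, p)
            parts = [nm / dn for nm, dn in ((n1, d1), (n2, d2)) if dn != 0]
            rij = float(np.mean(parts)) if parts else np.nan
            r[i, j] = r[j, i] = rij
            if not np.isnan(rij):
                vals.append(rij)
    frame = pd.DataFrame(r, index=ids, columns=ids)
    return frame, float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# Hardy–Weinberg, Welch
# ---------------------------------------------------------------------------

def hwe_test(locus_calls: np.ndarray) -> tuple[float, float]:
    """1-df chi-square of observed genotype counts against p², 2pq, q².

    Raises on monomorphic or nearly empty input (flagged not-testable).
    """
    calls = np.asarray(locus_calls)
    called = calls[calls != MISSING]
    n = called.size
    if n < 2:
        raise ValueError("HWE needs at least 2 called genotypes")
    p = called.sum() / (2 * n)
    if p in (0.0, 1.0):
        raise ValueError("HWE is not testable at a monomorphic locus")
    obs = np.array([(called == 0).sum(), (called == 1).sum(), (called == 2).sum()],
                   dtype=float)
    q = 1 - p
    exp = n * np.array([q * q, 2 * p * q, p * p])
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    undefined: bool = False   # both samples constant → the tables' N/A cells


def welch_t(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t statistic with Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        return WelchResult(t=np.nan, df=np.nan, p=np.nan, undefined=True)
    se2 = vx / len(x) + vy / len(y)
    t = float((x.mean() - y.mean()) / np.sqrt(se2))
    df = se2**2 / (vx**2 / (len(x) ** 2 * (len(x) - 1))
                   + vy**2 / (len(y) ** 2 * (len(y) - 1)))
    p = float(2 * stats.t.sf(abs(t), df))
    return WelchResult(t=t, df=float(df), p=p)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    var_among: float
    var_within: float
    pct_among: float
    pct_within: float
    phi: float
    p: float
    n_permutations: int
    truncated: bool = False


def _amova_components(d2: np.ndarray, groups: list[np.ndarray]):
    n_total = sum(len(g) for g in groups)
    k = len(groups)
    all_idx = np.concatenate(groups)
    sub = d2[np.ix_(all_idx, all_idx)]
    ss_total = sub[np.triu_indices(n_total, k=1)].sum() / n_total
    ss_within = 0.0
    for g in groups:
        dg = d2[np.ix_(g, g)]
        ss_within += dg[np.triu_indices(len(g), k=1)].sum() / len(g)
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, n_total - k
    ms_within = ss_within / df_within if df_within > 0 else np.nan
    ms_among = ss_among / df_among
    n0 = (n_total - sum(len(g) ** 2 for g in groups) / n_total) / df_among
    var_within = ms_within
    var_among = (ms_among - ms_within) / n0
    return ss_among, ss_within, df_among, df_within, var_among, var_within


def amova_two_level(
    dist: DistanceMatrix,
    pops: Mapping[str, Sequence[str]],
    n_permutations: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """Distance-based AMOVA partitioning variance among/within populations.

    Squared distances enter the sums of squares (Excoffier-style); the Phi
    statistic is var_among/(var_among + var_within) and its p-value comes
    from permuting population labels.  A negative among component is
    truncated to zero with a flag.
    """
    if len(pops) < 2:
        raise ValueError("AMOVA needs at least two populations")
    idx = {s: i for i, s in enumerate(dist.ids)}
    groups = [np.asarray([idx[s] for s in ids]) for ids in pops.values()]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every population needs at least two individuals")
    d2 = dist.d**2
    if np.isnan(d2[np.ix_(np.concatenate(groups), np.concatenate(groups))]).any():
        raise ValueError("distance matrix has undefined entries for AMOVA")

    ss_a, ss_w, df_a, df_w, var_a, var_w = _amova_components(d2, groups)
    truncated = var_a < 0
    var_a_t = max(var_a, 0.0)
    total = var_a_t + var_w
    phi = var_a_t / total if total > 0 else 0.0

    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    pool = np.concatenate(groups)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pool)
        offs = np.cumsum([0] + sizes)
        pg = [perm[offs[i]:offs[i + 1]] for i in range(len(sizes))]
        _, _, _, _, pa, pw = _amova_components(d2, pg)
        pa = max(pa, 0.0)
        ptot = pa + pw
        pphi = pa / ptot if ptot > 0 else 0.0
        if pphi >= phi - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1) if n_permutations else np.nan
    return AmovaResult(
        ss_among=ss_a, ss_within=ss_w, df_among=df_a, df_within=df_w,
        var_among=var_a_t, var_within=var_w,
        pct_among=100 * phi, pct_within=100 * (1 - phi),
        phi=phi, p=p, n_permutations=n_permutations, truncated=truncated,
    )
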