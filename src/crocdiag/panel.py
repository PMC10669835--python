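"""Species-diagnostic locus discovery and per-locus marker statistics.

A locus is species-diagnostic for species S when every called S individual
carries one fixed homozygous (SNP) or presence/absence (PA) state with zero
heterozygotes — the "100:0" criterion — and the other species differs.  Two
readings of "differs" are implemented:

* ``strict_absent`` — S's fixed allele is absent from every called
  individual of the other species (the most literal 100:0 reading);
* ``fixed_nonfixed`` (default) — the other species is simply not fixed for
  the same state.  This is the only reading compatible with strongly
  asymmetric panel sizes between two biallelic gene pools, and is therefore
  the default.

Reciprocally fixed loci satisfy both species' criteria; they are assigned
exclusively to one species by a configurable priority (default the focal
species A), so panel sizes add up to the total without double counting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dart_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

PANEL_MODES = ("strict_absent", "fixed_nonfixed")


@dataclass
class DiagnosticPanel:
    """Diagnostic loci with their assigned species and fixed state.

    ``entries`` has one row per locus: ``locus_id`` (index), ``species``
    ('A'/'B'), ``state`` (the fixed call code in the diagnostic species),
    ``status`` ('fixed_opposite' for reciprocally fixed loci, else
    'polymorphic'), ``marker_class``.
    """

    entries: pd.DataFrame
    mode: str

    def loci(self, species: str | None = None) -> pd.Index:
        if species is None:
            return self.entries.index
        return self.entries.index[self.entries["species"] == species]

    def __len__(self) -> int:
        return len(self.entries)

    def to_csv(self, path) -> None:
        self.entries.reset_index().to_csv(path, index=False)


def _fixed_state(calls: np.ndarray, marker_class: str) -> int | None:
    """The single fixed state of a called-genotype vector, or None.

    For SNPs a heterozygote anywhere disqualifies fixation; for PA markers
    the putative-heterozygosity code is already treated as missing upstream.
    """
    if calls.size == 0:
        return None
    first = calls[0]
    if not (calls == first).all():
        return None
    if marker_class == "snp" and first == 1:
        return None
    return int(first)


def find_diagnostic_loci(
    m: GenotypeMatrix,
    species_of: Mapping[str, str] | pd.Series | None = None,
    mode: str = "fixed_nonfixed",
    priority: str = "A",
    min_called_frac: float = 0.8,
    min_called: int = 2,
) -> DiagnosticPanel:
    """Identify diagnostic loci under the chosen mode.

    ``species_of`` maps sample ids to 'A'/'B'; samples not mapped (e.g.
    candidates) are excluded from frequency computation.  When omitted, the
    population labels are mapped with the package default (CSI → A,
    CPOTH/CPOAU → B).  Per locus, each species must have at least
    ``max(min_called, ceil(min_called_frac * n_species))`` called
    individuals; otherwise the locus is skipped with a log entry.
    """
    if mode not in PANEL_MODES:
        raise ValueError(f"mode must be one of {PANEL_MODES}")
    if priority not in ("A", "B"):
        raise ValueError("priority must be 'A' or 'B'")

    if species_of is None:
        masks = m.species_masks()
    else:
        sp = pd.Series(species_of)
        masks = {
            s: m.sample_ids.isin(sp.index[sp == s]).to_numpy() if hasattr(
                m.sample_ids.isin(sp.index[sp == s]), "to_numpy")
            else np.asarray(m.sample_ids.isin(sp.index[sp == s]))
            for s in ("A", "B")
        }
    for s in ("A", "B"):
        if s not in masks or not masks[s].any():
            raise ValueError(f"species {s!r} has no assigned samples")

    thresholds = {
        s: max(min_called, math.ceil(min_called_frac * masks[s].sum()))
        for s in ("A", "B")
    }
    other = {"A": "B", "B": "A"}
    rows = []
    n_skipped = 0
    marker_classes = m.loci["marker_class"].to_numpy()
    for i, locus_id in enumerate(m.locus_ids):
        mc = marker_classes[i]
        calls = {s: m.calls[i, masks[s]] for s in ("A", "B")}
        called = {s: calls[s][calls[s] != MISSING] for s in ("A", "B")}
        if any(called[s].size < thresholds[s] for s in ("A", "B")):
            n_skipped += 1
            continue
        fixed = {s: _fixed_state(called[s], mc) for s in ("A", "B")}

        def qualifies(s: str) -> bool:
            st = fixed[s]
            if st is None:
                return False
            oc = called[other[s]]
            if mode == "fixed_nonfixed":
                return fixed[other[s]] != st
            # strict_absent: S's fixed allele absent from the other species
            if mc == "pa":
                return bool((oc != st).all())
            if st == 0:      # fixed reference homozygote: ref allele absent
                return bool((oc == 2).all())
            return bool((oc == 0).all())   # fixed alt homozygote

        qa, qb = qualifies("A"), qualifies("B")
        if qa and qb:
            s = priority
            rows.append((locus_id, s, fixed[s], "fixed_opposite", mc))
        elif qa:
            rows.append((locus_id, "A", fixed["A"], "polymorphic", mc))
        elif qb:
            rows.append((locus_id, "B", fixed["B"], "polymorphic", mc))

    if n_skipped:
        logger.info("find_diagnostic_loci: %d loci skipped for insufficient calls",
                    n_skipped)
    entries = pd.DataFrame(
        rows, columns=["locus_id", "species", "state", "status", "marker_class"]
    ).set_index("locus_id")
    return DiagnosticPanel(entries=entries, mode=mode)


# ---------------------------------------------------------------------------
# Cochran–Armitage trend test
# ---------------------------------------------------------------------------

def catt_from_table(table, scores: Sequence[float] | None = None) -> tuple[float, float]:
    """Trend chi-square and p-value for a 2 × k contingency table.

    ``table[r][j]`` counts group r individuals in ordered category j with
    trend score ``scores[j]`` (default 0..k−1).  The statistic is
    T² / Var(T) with T = Σⱼ sⱼ (n₁ⱼR₂ − n₂ⱼR₁) and the N-denominator
    variance, so complete separation of two groups yields exactly N on the
    0/1 score scale.  Referred to χ²₁.
    """
    t = np.asarray(table, dtype=float)
    if t.shape[0] != 2:
        raise ValueError("table must have exactly two rows (groups)")
    k = t.shape[1]
    s = np.arange(k, dtype=float) if scores is None else np.asarray(scores, float)
    if s.shape != (k,):
        raise ValueError("scores length must match table columns")
    n_cols = t.sum(axis=0)
    r1, r2 = t.sum(axis=1)
    n = t.sum()
    if n == 0 or r1 == 0 or r2 == 0:
        return 0.0, 1.0
    T = float(np.sum(s * (t[0] * r2 - t[1] * r1)))
    var = float(
        r1 * r2 / n
        * (np.sum(s**2 * n_cols * (n - n_cols))
           - 2 * sum(s[j] * s[kk] * n_cols[j] * n_cols[kk]
                     for j in range(k) for kk in range(j + 1, k)))
    )
    if var <= 0:
        return 0.0, 1.0   # no variation in the ordered categories
    chi2 = T * T / var
    return chi2, float(stats.chi2.sf(chi2, df=1))


def catt_association(
    locus_calls: np.ndarray,
    species_labels: Sequence[str],
    scale: str = "genotype",
    marker_class: str = "snp",
) -> tuple[float, float]:
    """Association between one locus and species membership.

    ``scale='genotype'`` scores individuals (SNP 0/1/2, PA 0/1);
    ``scale='allele'`` counts 2 allele copies per called SNP individual in a
    2 × 2 table.  Monomorphic loci return (0, 1).
    """
    calls = np.asarray(locus_calls)
    labels = np.asarray(species_labels)
    called = calls != MISSING
    calls, labels = calls[called], labels[called]
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError("exactly two species groups are required")
    if any((labels == g).sum() < 1 for g in groups):
        raise ValueError("each group needs at least one called individual")

    if scale == "genotype":
        cats = [0, 1, 2] if marker_class == "snp" else [0, 1]
        table = [[(calls[labels == g] == c).sum() for c in cats] for g in groups]
    elif scale == "allele":
        if marker_class != "snp":
            raise ValueError("allele scale applies to SNP loci only")
        table = [
            [
                int((2 * (calls[labels == g] == 0) + (calls[labels == g] == 1)).sum()),
                int((2 * (calls[labels == g] == 2) + (calls[labels == g] == 1)).sum()),
            ]
            for g in groups
        ]
    else:
        raise ValueError("scale must be 'genotype' or 'allele'")
    return catt_from_table(table)


# ---------------------------------------------------------------------------
# locus informativeness
# ---------------------------------------------------------------------------

def pic_index(p: Sequence[float], botstein: bool = False) -> float:
    """Polymorphic information content of a locus.

    The default is the expected-heterozygosity form 1 − Σp², which runs from
    0 at fixation to 0.5 at equal biallelic frequencies.  ``botstein=True``
    gives the three-term form 1 − Σp² − ΣΣ_{i<j} 2pᵢ²pⱼ² (maximum 0.375 for
    biallelic loci).
    """
    p = np.asarray(p, dtype=float)
    if (p < -1e-12).any() or abs(p.sum() - 1) > 1e-9:
        raise ValueError(f"allele frequencies must be a simplex, got {p}")
    base = 1.0 - float(np.sum(p**2))
    if not botstein:
        return base
    cross = sum(
        2 * p[i] ** 2 * p[j] ** 2 for i in range(len(p)) for j in range(i + 1, len(p))
    )
    return base - float(cross)


# ---------------------------------------------------------------------------
# Hamming distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Proportional pairwise distances with per-pair locus counts.

    ``d[i, j]`` is the fraction of co-called loci at which the two call
    vectors differ; NaN when a pair shares no called locus (``n_compared``
    records the co-called counts).
    """

    ids: pd.Index
    d: np.ndarray
    n_compared: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.n_compared = np.asarray(self.n_compared, dtype=int)

    @property
    def undefined_pairs(self) -> np.ndarray:
        out = self.n_compared == 0
        np.fill_diagonal(out, False)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def to_long_csv(self, path) -> None:
        """Heatmap-ready long format: sample_i, sample_j, distance, n_loci."""
        rows = [
            (self.ids[i], self.ids[j], self.d[i, j], self.n_compared[i, j])
            for i in range(len(self.ids)) for j in range(len(self.ids))
        ]
        pd.DataFrame(rows, columns=["sample_i", "sample_j", "distance", "n_loci"]
                     ).to_csv(path, index=False)

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = np.asarray([self.ids.get_loc(i) for i in ids])
        return DistanceMatrix(pd.Index(ids, name=self.ids.name),
                              self.d[np.ix_(idx, idx)],
                              self.n_compared[np.ix_(idx, idx)])


def hamming_matrix(m: GenotypeMatrix, locus_subset=None) -> DistanceMatrix:
    """Proportional Hamming distance between all individual pairs.

    Only loci called in both individuals of a pair are compared; pairs with
    zero co-called loci are flagged undefined (NaN).
    """
    sub = m if locus_subset is None else m.take_loci(
        m.locus_ids.isin(pd.Index(locus_subset)))
    if sub.n_loci == 0:
        raise ValueError("locus subset is empty")
    calls = sub.calls
    called = calls != MISSING
    n = sub.n_samples
    d = np.zeros((n, n))
    n_comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = called[:, i][:, None] & called[:, i + 1:]
        diff = (calls[:, i][:, None] != calls[:, i + 1:]) & both
        nc = both.sum(axis=0)
        nd = diff.sum(axis=0)
        with np.errstate(invalid="ignore"):
            dij = np.where(nc > 0, nd / np.maximum(nc, 1), np.nan)
        d[i, i + 1:] = d[i + 1:, i] = dij
        n_comp[i, i + 1:] = n_comp[i + 1:, i] = nc
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(n_comp, called.sum(axis=0))
    if np.isnan(d).any():
        logger.warning("hamming_matrix: %d pairs share no called locus",
                       int(np.isnan(d).sum() // 2))
    return DistanceMatrix(ids=sub.sample_ids, d=d, n_compared=n_comp)


# ---------------------------------------------------------------------------
# consensus identity
# ---------------------------------------------------------------------------

def _consensus(calls: np.ndarray) -> np.ndarray:
    """Majority non-missing code per locus; ties broken by the lowest code;
    all-missing loci yield MISSING."""
    n_loci = calls.shape[0]
    out = np.full(n_loci, MISSING, dtype=np.int8)
    for i in range(n_loci):
        row = calls[i][calls[i] != MISSING]
        if row.size == 0:
            continue
        codes, counts = np.unique(row, return_counts=True)
        out[i] = codes[np.argmax(counts)]   # np.unique sorts: tie → lowest code
    return out


def consensus_identity(mA: GenotypeMatrix, mB: GenotypeMatrix) -> dict:
    """Between-group conservation summary over a shared locus set.

    Returns ``identical_sites_pct`` — the percentage of loci whose two
    group-consensus calls agree — and ``pairwise_identity_pct`` — the mean
    over all between-group individual pairs of the percentage of co-called
    identical loci.  Loci where either consensus is undefined (all missing)
    are excluded and counted.
    """
    if not mA.locus_ids.equals(mB.locus_ids):
        raise ValueError("groups must share the same locus set")
    ca, cb = _consensus(mA.calls), _consensus(mB.calls)
    defined = (ca != MISSING) & (cb != MISSING)
    n_excluded = int((~defined).sum())
    if defined.sum() == 0:
        raise ValueError("no locus has a defined consensus in both groups")
    identical_pct = 100.0 * float((ca[defined] == cb[defined]).mean())

    ids = []
    calls = np.hstack([mA.calls, mB.calls])
    na = mA.n_samples
    called = calls != MISSING
    for i in range(na):
        for j in range(na, na + mB.n_samples):
            both = called[:, i] & called[:, j]
            if both.sum():
                ids.append(float((calls[both, i] == calls[both, j]).mean()))
    pairwise_pct = 100.0 * float(np.mean(ids)) if ids else float("nan")
    return {
        "identical_sites_pct": identical_pct,
        "pairwise_identity_pct": pairwise_pct,
        "n_loci_excluded": n_excluded,
    }


def within_identity(m: GenotypeMatrix) -> dict:
    """Within-group conservation: % of loci where all called individuals agree,
    and the mean pairwise identity % between individuals."""
    called = m.calls != MISSING
    any_called = called.any(axis=1)
    identical = np.zeros(m.n_loci, dtype=bool)
    for i in np.flatnonzero(any_called):
        row = m.calls[i][called[i]]
        identical[i] = (row == row[0]).all()
    identical_pct = 100.0 * float(identical[any_called].mean())
    vals = []
    for i in range(m.n_samples):
        for j in range(i + 1, m.n_samples):
            both = called[:, i] & called[:, j]
            if both.sum():
                vals.append(float((m.calls[both, i] == m.calls[both, j]).mean()))
    return {
        "identical_sites_pct": identical_pct,
        "pairwise_identity_pct": 100.0 * float(np.mean(vals)) if vals else float("nan"),
        "n_loci_excluded": int((~any_called).sum()),
    }
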