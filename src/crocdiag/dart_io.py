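"""Reading, writing, validation and quality filtering of DArT-style genotype matrices.

Two marker classes are supported:

* ``snp`` — codominant SNP loci coded ``0`` (reference homozygote), ``1``
  (heterozygote), ``2`` (alternate homozygote), ``-`` (missing);
* ``pa`` — dominant presence/absence loci from restriction-site tags, coded
  ``1`` (presence), ``0`` (absence), ``-`` (putative heterozygosity /
  missing).

The on-disk dialect is a single CSV per marker class: rows are loci, the
first nine columns carry locus metadata (``locus_id, contig, position, ref,
alt, depth, reproducibility, call_rate, marker_class``), every remaining
column is one sample.  Positions are 1-based inclusive.  Sample metadata
travels in a separate CSV (``sample_id, population, mtdna_haplotype,
external_q`` plus optional ``band_<marker>`` columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Internal sentinel for a missing call.
MISSING = -1

#: Canonical missing symbol on disk; aliases accepted on read.
MISSING_SYMBOL = "-"
MISSING_ALIASES = {"-", "−", "NA", "", "nan", "NaN"}

LOCUS_META_COLUMNS = [
    "locus_id", "contig", "position", "ref", "alt",
    "depth", "reproducibility", "call_rate", "marker_class",
]

LEGAL_CODES = {"snp": {0, 1, 2}, "pa": {0, 1}}

POPULATIONS = {"CSI", "CPOTH", "CPOAU", "CANDIDATE"}

#: Default mapping of population labels to the two parental species.
#: Species "A" is the focal (endangered) species, "B" the other parental
#: species; CANDIDATE individuals are of unknown ancestry.
DEFAULT_SPECIES_OF_POP = {"CSI": "A", "CPOTH": "B", "CPOAU": "B"}


class DartIOError(ValueError):
    """Malformed input file or illegal genotype code."""


@dataclass
class FilterReport:
    """Per-criterion accounting for one filter_loci call."""

    n_input: int
    n_fail_reproducibility: int
    n_fail_call_rate: int
    n_fail_depth: int
    n_retained: int
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": [
                    "input", "fail_reproducibility", "fail_call_rate",
                    "fail_depth", "retained",
                ],
                "n_loci": [
                    self.n_input, self.n_fail_reproducibility,
                    self.n_fail_call_rate, self.n_fail_depth, self.n_retained,
                ],
            }
        )


@dataclass
class GenotypeMatrix:
    """Loci × samples call matrix with locus and sample metadata.

    ``calls`` is an ``int8`` array with :data:`MISSING` (−1) for missing
    calls; ``loci`` is indexed by ``locus_id`` and carries the metadata
    columns listed in :data:`LOCUS_META_COLUMNS` (minus the id); ``samples``
    is indexed by ``sample_id``.
    """

    calls: np.ndarray
    loci: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.loci), len(self.samples)):
            raise DartIOError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )
        self.validate_codes()

    # -- basic accessors ---------------------------------------------------
    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def locus_ids(self) -> pd.Index:
        return self.loci.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index

    def validate_codes(self) -> None:
        """Check that every call is a legal code for its marker class."""
        mc = self.loci["marker_class"].to_numpy()
        for cls, legal in LEGAL_CODES.items():
            rows = mc == cls
            if not rows.any():
                continue
            sub = self.calls[rows]
            bad = (sub != MISSING) & ~np.isin(sub, sorted(legal))
            if bad.any():
                li, si = np.argwhere(bad)[0]
                locus = self.loci.index[np.flatnonzero(rows)[li]]
                sample = self.samples.index[si]
                raise DartIOError(
                    f"illegal {cls} code {sub[li, si]} at locus {locus!r}, "
                    f"sample {sample!r}"
                )
        unknown = set(mc) - set(LEGAL_CODES)
        if unknown:
            raise DartIOError(f"unknown marker_class values: {sorted(unknown)}")

    def recomputed_call_rate(self) -> np.ndarray:
        """Fraction of samples with a non-missing call, per locus."""
        return (self.calls != MISSING).mean(axis=1)

    # -- subsetting --------------------------------------------------------
    def take_loci(self, which) -> "GenotypeMatrix":
        """Subset loci by boolean mask, positional indices, or locus ids."""
        idx = self._resolve(which, self.loci.index)
        return GenotypeMatrix(self.calls[idx], self.loci.iloc[idx].copy(),
                              self.samples.copy())

    def take_samples(self, which) -> "GenotypeMatrix":
        idx = self._resolve(which, self.samples.index)
        return GenotypeMatrix(self.calls[:, idx], self.loci.copy(),
                              self.samples.iloc[idx].copy())

    @staticmethod
    def _resolve(which, index: pd.Index) -> np.ndarray:
        arr = np.asarray(which)
        if arr.dtype == bool:
            return np.flatnonzero(arr)
        if arr.dtype.kind in "iu":
            return arr
        return np.asarray([index.get_loc(x) for x in arr])

    def species_masks(
        self, species_of_pop: Mapping[str, str] | None = None
    ) -> dict[str, np.ndarray]:
        """Boolean sample masks per species label (candidates excluded)."""
        mapping = DEFAULT_SPECIES_OF_POP if species_of_pop is None else species_of_pop
        pops = self.samples["population"]
        out: dict[str, np.ndarray] = {}
        for sp in sorted(set(mapping.values())):
            members = [p for p, s in mapping.items() if s == sp]
            out[sp] = pops.isin(members).to_numpy()
        return out

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.copy(), self.loci.copy(), self.samples.copy())


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _decode_calls(raw: pd.DataFrame, marker_class: np.ndarray) -> np.ndarray:
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    values = raw.to_numpy(dtype=object)
    for i in range(values.shape[0]):
        legal = LEGAL_CODES[marker_class[i]]
        for j in range(values.shape[1]):
            v = values[i, j]
            s = "" if v is None or (isinstance(v, float) and np.isnan(v)) else str(v).strip()
            if s in MISSING_ALIASES:
                continue
            try:
                code = int(s)
            except ValueError:
                code = None
            if code is None or code not in legal:
                raise DartIOError(
                    f"illegal code {s!r} at locus {raw.index[i]!r}, "
                    f"sample {raw.columns[j]!r}"
                )
            calls[i, j] = code
    return calls


def read_genotype_csv(path: str | Path, marker_class: str) -> GenotypeMatrix:
    """Read a genotype CSV in the documented dialect.

    ``marker_class`` ({"snp", "pa"}) declares what the file must contain;
    a mismatching ``marker_class`` column is a validation error.
    """
    if marker_class not in LEGAL_CODES:
        raise DartIOError(f"marker_class must be one of {sorted(LEGAL_CODES)}")
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in LOCUS_META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DartIOError(
            f"{path.name}: malformed header (line 1): missing metadata "
            f"columns {missing_cols}"
        )
    sample_cols = [c for c in df.columns if c not in LOCUS_META_COLUMNS]
    if not sample_cols:
        raise DartIOError(f"{path.name}: header names no sample columns")
    if df["locus_id"].duplicated().any():
        dup = df["locus_id"][df["locus_id"].duplicated()].iloc[0]
        raise DartIOError(f"duplicate locus_id {dup!r}")

    loci = df[LOCUS_META_COLUMNS].copy()
    loci["position"] = loci["position"].astype(int)
    for col in ("depth", "reproducibility", "call_rate"):
        loci[col] = loci[col].astype(float)
    loci = loci.set_index("locus_id")
    bad_class = loci.index[loci["marker_class"] != marker_class]
    if len(bad_class):
        raise DartIOError(
            f"locus {bad_class[0]!r} has marker_class "
            f"{loci.loc[bad_class[0], 'marker_class']!r}, expected {marker_class!r}"
        )
    if (loci["position"] < 1).any():
        bad = loci.index[loci["position"] < 1][0]
        raise DartIOError(f"locus {bad!r}: position must be >= 1")
    if marker_class == "snp":
        same = loci.index[loci["ref"] == loci["alt"]]
        if len(same):
            raise DartIOError(f"locus {same[0]!r}: ref and alt alleles identical")

    raw = df[sample_cols].copy()
    raw.index = loci.index
    calls = _decode_calls(raw, loci["marker_class"].to_numpy())
    samples = pd.DataFrame(index=pd.Index(sample_cols, name="sample_id"))
    samples["population"] = "CANDIDATE"
    return GenotypeMatrix(calls, loci, samples)


def write_genotype_csv(m: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix in the canonical dialect (round-trips exactly)."""
    out = m.loci.reset_index()[LOCUS_META_COLUMNS].copy()
    coded = m.calls.astype(object)
    coded[m.calls == MISSING] = MISSING_SYMBOL
    for j, sid in enumerate(m.sample_ids):
        out[sid] = coded[:, j]
    out.to_csv(path, index=False)


def read_sample_csv(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata CSV, validating populations and q values."""
    df = pd.read_csv(Path(path), dtype={"sample_id": str})
    if "sample_id" not in df.columns or "population" not in df.columns:
        raise DartIOError("sample CSV needs 'sample_id' and 'population' columns")
    df = df.set_index("sample_id")
    bad = set(df["population"]) - POPULATIONS
    if bad:
        raise DartIOError(f"unknown population labels: {sorted(bad)}")
    if "external_q" in df.columns:
        q = df["external_q"]
        if ((q < 0) | (q > 1)).any():
            raise DartIOError("external_q must lie in [0, 1]")
    return df


def write_sample_csv(samples: pd.DataFrame, path: str | Path) -> None:
    samples.reset_index().to_csv(path, index=False)


def attach_sample_metadata(m: GenotypeMatrix, samples: pd.DataFrame) -> GenotypeMatrix:
    """Return a matrix whose sample table is replaced by `samples` (id-aligned)."""
    missing = [s for s in m.sample_ids if s not in samples.index]
    if missing:
        raise DartIOError(f"sample metadata missing ids: {missing[:5]}")
    return GenotypeMatrix(m.calls, m.loci.copy(), samples.loc[m.sample_ids].copy())


# ---------------------------------------------------------------------------
# quality filtering
# ---------------------------------------------------------------------------

def filter_loci(
    m: GenotypeMatrix,
    min_reproducibility: float = 0.0,
    min_call_rate: float = 0.0,
    min_depth: float = 0.0,
    return_report: bool = False,
):
    """Retain loci with reproducibility, recomputed call rate and depth all
    strictly above their thresholds.

    The call rate is always recomputed from the calls, never trusted from the
    metadata column.  Thresholds of 0 act as no-ops on complete data.  An
    empty result is a warning, not an error.
    """
    for name, thr in (("min_reproducibility", min_reproducibility),
                      ("min_call_rate", min_call_rate),
                      ("min_depth", min_depth)):
        if not np.isfinite(thr) or thr < 0:
            raise ValueError(f"{name} must be finite and non-negative, got {thr}")

    call_rate = m.recomputed_call_rate()
    ok_rep = m.loci["reproducibility"].to_numpy() > min_reproducibility
    ok_cr = call_rate > min_call_rate
    ok_dp = m.loci["depth"].to_numpy() > min_depth
    # threshold 0 is documented as a no-op, including for all-zero columns
    if min_reproducibility == 0:
        ok_rep[:] = True
    if min_call_rate == 0:
        ok_cr[:] = True
    if min_depth == 0:
        ok_dp[:] = True
    keep = ok_rep & ok_cr & ok_dp
    report = FilterReport(
        n_input=m.n_loci,
        n_fail_reproducibility=int((~ok_rep).sum()),
        n_fail_call_rate=int((~ok_cr).sum()),
        n_fail_depth=int((~ok_dp).sum()),
        n_retained=int(keep.sum()),
        thresholds={"min_reproducibility": min_reproducibility,
                    "min_call_rate": min_call_rate, "min_depth": min_depth},
    )
    logger.info(
        "filter_loci: %d/%d retained (fail repro %d, call rate %d, depth %d)",
        report.n_retained, report.n_input, report.n_fail_reproducibility,
        report.n_fail_call_rate, report.n_fail_depth,
    )
    if report.n_retained == 0:
        logger.warning("filter_loci: no loci passed the filters")
    out = m.take_loci(keep)
    out.loci["call_rate"] = call_rate[keep]
    return (out, report) if return_report else out


DEPTH_TIERS = (5.0, 10.0, 15.0)


def depth_tiers(m: GenotypeMatrix) -> dict[int, GenotypeMatrix]:
    """The three nested depth-tier datasets (>5X, >10X, >15X)."""
    if m.loci["depth"].isna().any():
        raise DartIOError("depth must be present for every locus")
    tiers: dict[int, GenotypeMatrix] = {}
    for bound in DEPTH_TIERS:
        tier = filter_loci(m, min_depth=bound)
        if tier.n_loci == 0:
            logger.warning("depth tier >%gX is empty", bound)
        tiers[int(bound)] = tier
    return tiers


def pool_as_snp(snp_m: GenotypeMatrix, pa_m: GenotypeMatrix) -> GenotypeMatrix:
    """Pool SNP and PA loci into one SNP-coded matrix for genetic analyses.

    Dominant PA states are scored as homozygotes (presence → 2, absence → 0),
    the convention used when PA tags are pooled with SNP loci; the resulting
    heterozygosity is an underestimate for the PA fraction.
    """
    if not snp_m.sample_ids.equals(pa_m.sample_ids):
        raise DartIOError("SNP and PA matrices must share the same samples")
    pa_calls = pa_m.calls.copy()
    pa_calls[pa_calls == 1] = 2
    pa_loci = pa_m.loci.copy()
    pa_loci["marker_class"] = "snp"
    calls = np.vstack([snp_m.calls, pa_calls])
    loci = pd.concat([snp_m.loci, pa_loci])
    if loci.index.duplicated().any():
        raise DartIOError("locus ids collide between SNP and PA matrices")
    return GenotypeMatrix(calls, loci, snp_m.samples.copy())
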