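"""Synthetic parental gene pools and Mendelian hybrid pedigrees.

The generator emulates the structure of a two-species DArT genotype study:
two long-diverged parental populations genotyped at biallelic tag loci,
with locus categories

* ``reciprocal_fixed`` — fixed for opposite homozygotes in the two species
  (the ideal species-diagnostic locus);
* ``A_fixed_B_poly`` / ``B_fixed_A_poly`` — fixed in the focal species,
  polymorphic in the other (the asymmetric part of a diagnostic panel);
* ``shared_poly`` — polymorphic in both species (shared ancestral
  variation);
* ``monomorphic`` — invariant everywhere.

Category labels refer to the *realized sample*: loci in a polymorphic
category are resampled until both alleles are actually observed in the
relevant species, so the simulated truth is exact, not merely expected.

Hybrids are produced by Mendelian gamete sampling with free recombination
(loci unlinked): F1 = A×B, F2 = F1×F1, BC1 = F1×parent, BC2 = BC1×parent.
A hidden diploid genotype is kept for every individual (including at
dominant PA loci and under call masking) so pedigrees can be extended and
tests can check Mendelian expectations exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .dart_io import (
    MISSING, GenotypeMatrix, read_genotype_csv, read_sample_csv,
    write_genotype_csv, write_sample_csv, attach_sample_metadata,
)

LOCUS_CATEGORIES = (
    "reciprocal_fixed", "A_fixed_B_poly", "B_fixed_A_poly",
    "shared_poly", "monomorphic",
)

HYBRID_CLASSES = ("F1", "F2", "BC1_toA", "BC1_toB", "BC2_toA", "BC2_toB")

#: Expected minor-parent diagnostic-allele fraction per pedigree class;
#: halves with every backcross generation.
EXPECTED_MINOR_FRACTION = {
    "F1": 0.5, "F2": 0.5,
    "BC1_toA": 0.25, "BC1_toB": 0.25,
    "BC2_toA": 0.125, "BC2_toB": 0.125,
}


def _default_pedigree_counts() -> dict[str, int]:
    return {c: 4 for c in HYBRID_CLASSES}


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults mirror the structure of the crocodile study: 29 focal-species
    (A) and 30 other-species (B) individuals, the B population split
    12 Thai / 18 Australian, and a strongly A-skewed diagnostic panel
    (skew 0.86 ≈ 8051/9339).
    """

    n_loci: int = 2000
    frac_reciprocal_fixed: float = 0.10
    frac_focal_fixed_other_poly: float = 0.20
    focal_fixed_skew: float = 0.86   # share of focal-fixed loci fixed in A
    frac_shared_poly: float = 0.35   # remainder of n_loci is monomorphic
    frac_pa: float = 0.0             # fraction of loci emitted as dominant PA
    n_A: int = 29
    n_B: int = 30
    n_B_au: int = 18                 # of n_B, how many labelled CPOAU
    pedigree_counts: dict[str, int] = field(default_factory=_default_pedigree_counts)
    missing_rate: float = 0.02
    depth_median: float = 12.0       # lognormal depth law
    depth_sigma: float = 0.5
    poly_freq_low: float = 0.1       # allele-frequency law for polymorphic loci
    poly_freq_high: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        total = (self.frac_reciprocal_fixed + self.frac_focal_fixed_other_poly
                 + self.frac_shared_poly)
        if total > 1 + 1e-12:
            raise ValueError(f"locus category fractions sum to {total} > 1")
        for name in ("frac_reciprocal_fixed", "frac_focal_fixed_other_poly",
                     "frac_shared_poly", "focal_fixed_skew", "frac_pa"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_A < 0 or self.n_B < 0 or self.n_B_au > self.n_B:
            raise ValueError("invalid population sizes")
        if any(v < 0 for v in self.pedigree_counts.values()):
            raise ValueError("pedigree counts must be non-negative")
        unknown = set(self.pedigree_counts) - set(HYBRID_CLASSES)
        if unknown:
            raise ValueError(f"unknown pedigree classes: {sorted(unknown)}")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated matrix.

    ``diploid`` holds the hidden, unmasked diploid genotypes (0/1/2 alt-allele
    dosage) for every individual at every locus, including loci that the
    emitted matrix codes dominantly (PA) or masks as missing.
    """

    locus_category: pd.Series      # index locus_id
    pedigree_class: pd.Series      # index sample_id
    diploid: np.ndarray            # loci x samples, int8

    def expected_minor_fraction(self, sample_id: str) -> float:
        cls = self.pedigree_class.loc[sample_id]
        return EXPECTED_MINOR_FRACTION.get(cls, 0.0)


# ---------------------------------------------------------------------------
# parental populations
# ---------------------------------------------------------------------------

def _category_counts(cfg: SimConfig) -> dict[str, int]:
    n = cfg.n_loci
    n_rec = round(cfg.frac_reciprocal_fixed * n)
    n_focal = round(cfg.frac_focal_fixed_other_poly * n)
    n_a_fixed = round(cfg.focal_fixed_skew * n_focal)
    n_b_fixed = n_focal - n_a_fixed
    n_shared = round(cfg.frac_shared_poly * n)
    n_mono = n - n_rec - n_focal - n_shared
    if n_mono < 0:
        raise ValueError("locus category fractions overflow n_loci")
    return {
        "reciprocal_fixed": n_rec,
        "A_fixed_B_poly": n_a_fixed,
        "B_fixed_A_poly": n_b_fixed,
        "shared_poly": n_shared,
        "monomorphic": n_mono,
    }


def _sample_polymorphic(rng: np.random.Generator, n_ind: int, low: float,
                        high: float, marker_class: str = "snp") -> np.ndarray:
    """Genotypes for one locus, guaranteed polymorphic in the realized sample.

    For SNP loci "polymorphic" means both alleles observed; for dominant PA
    loci it means both emitted presence states observed (at least one
    carrier and one non-carrier), so the truth category stays exact under
    the dominant coding.
    """
    if n_ind < 2:   # polymorphism unobservable; category is vacuous
        return rng.binomial(2, rng.uniform(low, high), size=n_ind).astype(np.int8)
    while True:
        p = rng.uniform(low, high)
        g = rng.binomial(2, p, size=n_ind).astype(np.int8)
        if marker_class == "pa":
            if 0 < int((g >= 1).sum()) < n_ind:
                return g
        else:
            alt = int(g.sum())
            if 0 < alt < 2 * n_ind:
                return g


def simulate_parentals(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Two diverged parental populations under Hardy–Weinberg sampling."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    counts = _category_counts(cfg)
    n_ind = cfg.n_A + cfg.n_B
    categories = np.repeat(list(counts), list(counts.values()))
    rng.shuffle(categories)

    loci = _make_locus_table(cfg, rng)
    marker_class = loci["marker_class"].to_numpy()
    diploid = np.zeros((cfg.n_loci, n_ind), dtype=np.int8)
    a = slice(0, cfg.n_A)
    b = slice(cfg.n_A, n_ind)
    for i, cat in enumerate(categories):
        mc = marker_class[i]
        if cat == "reciprocal_fixed":
            a_state = 0 if rng.random() < 0.5 else 2   # orientation random
            diploid[i, a] = a_state
            diploid[i, b] = 2 - a_state
        elif cat == "A_fixed_B_poly":
            a_state = 0 if rng.random() < 0.5 else 2
            diploid[i, a] = a_state
            diploid[i, b] = _sample_polymorphic(
                rng, cfg.n_B, cfg.poly_freq_low, cfg.poly_freq_high, mc)
        elif cat == "B_fixed_A_poly":
            b_state = 0 if rng.random() < 0.5 else 2
            diploid[i, b] = b_state
            diploid[i, a] = _sample_polymorphic(
                rng, cfg.n_A, cfg.poly_freq_low, cfg.poly_freq_high, mc)
        elif cat == "shared_poly":
            diploid[i, a] = _sample_polymorphic(
                rng, cfg.n_A, cfg.poly_freq_low, cfg.poly_freq_high, mc)
            diploid[i, b] = _sample_polymorphic(
                rng, cfg.n_B, cfg.poly_freq_low, cfg.poly_freq_high, mc)
        # monomorphic: all reference homozygotes
    samples = _make_parental_samples(cfg)
    calls = _emit_calls(diploid, loci, cfg.missing_rate, rng)
    m = GenotypeMatrix(calls, loci, samples)
    m.loci["call_rate"] = m.recomputed_call_rate()
    truth = SimTruth(
        locus_category=pd.Series(categories, index=loci.index, name="locus_category"),
        pedigree_class=pd.Series(
            ["pureA"] * cfg.n_A + ["pureB"] * cfg.n_B,
            index=samples.index, name="pedigree_class"),
        diploid=diploid,
    )
    return m, truth


def _make_locus_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_loci
    ids = [f"L{i + 1:06d}" for i in range(n)]
    n_pa = round(cfg.frac_pa * n)
    marker_class = np.array(["snp"] * n, dtype=object)
    if n_pa:
        marker_class[rng.choice(n, size=n_pa, replace=False)] = "pa"
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    depth = rng.lognormal(mean=np.log(cfg.depth_median), sigma=cfg.depth_sigma, size=n)
    loci = pd.DataFrame(
        {
            "contig": [f"contig_{i // 50 + 1}" for i in range(n)],
            "position": [(i % 50) * 200 + 101 for i in range(n)],
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
            "depth": np.round(depth, 2),
            "reproducibility": np.round(rng.uniform(0.92, 1.0, size=n), 4),
            "call_rate": 1.0,
            "marker_class": marker_class,
        },
        index=pd.Index(ids, name="locus_id"),
    )
    return loci


def _make_parental_samples(cfg: SimConfig) -> pd.DataFrame:
    ids = [f"CSI{i + 1:02d}" for i in range(cfg.n_A)]
    n_th = cfg.n_B - cfg.n_B_au
    ids += [f"CPO{i + 1:02d}" for i in range(cfg.n_B)]
    pops = (["CSI"] * cfg.n_A + ["CPOTH"] * n_th + ["CPOAU"] * cfg.n_B_au)
    mt = ["A-species"] * cfg.n_A + ["B-species"] * cfg.n_B
    return pd.DataFrame(
        {"population": pops, "mtdna_haplotype": mt},
        index=pd.Index(ids, name="sample_id"),
    )


def _emit_calls(diploid: np.ndarray, loci: pd.DataFrame, missing_rate: float,
                rng: np.random.Generator) -> np.ndarray:
    """Dominant-code PA loci and apply independent call masking."""
    calls = diploid.copy()
    pa_rows = (loci["marker_class"] == "pa").to_numpy()
    if pa_rows.any():
        # presence allele = alt, dominant: any alt copy shows the band
        calls[pa_rows] = (diploid[pa_rows] >= 1).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = MISSING
    return calls


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

def _gametes(diploid_cols: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One independently sampled allele per locus (free recombination)."""
    return rng.binomial(1, diploid_cols / 2.0).astype(np.int8)


def simulate_pedigree(
    parents: GenotypeMatrix, truth: SimTruth, cfg: SimConfig,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Extend a parental matrix with Mendelian hybrid individuals.

    Returns the combined matrix (parents first, then hybrids, populations
    labelled CANDIDATE) and the extended truth.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    is_a = (truth.pedigree_class == "pureA").to_numpy()
    is_b = (truth.pedigree_class == "pureB").to_numpy()
    counts = {c: int(cfg.pedigree_counts.get(c, 0)) for c in HYBRID_CLASSES}
    if any(counts.values()) and (not is_a.any() or not is_b.any()):
        raise ValueError("hybrids requested but a parental population is empty")

    dip = truth.diploid

    def pick(mask: np.ndarray) -> np.ndarray:
        return dip[:, rng.choice(np.flatnonzero(mask))]

    def cross(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
        return _gametes(g1, rng) + _gametes(g2, rng)

    new_dip, new_ids, new_cls = [], [], []
    for cls in HYBRID_CLASSES:
        for k in range(counts[cls]):
            f1 = cross(pick(is_a), pick(is_b))
            if cls == "F1":
                child = f1
            elif cls == "F2":
                f1b = cross(pick(is_a), pick(is_b))
                child = cross(f1, f1b)
            elif cls in ("BC1_toA", "BC1_toB"):
                par = pick(is_a if cls.endswith("A") else is_b)
                child = cross(f1, par)
            else:  # BC2
                mask = is_a if cls.endswith("A") else is_b
                bc1 = cross(f1, pick(mask))
                child = cross(bc1, pick(mask))
            new_dip.append(child)
            new_ids.append(f"{cls}_{k + 1:02d}")
            new_cls.append(cls)

    if not new_dip:
        return parents, truth

    hyb_dip = np.column_stack(new_dip)
    hyb_calls = _emit_calls(hyb_dip, parents.loci, cfg.missing_rate, rng)
    hyb_samples = pd.DataFrame(
        {"population": "CANDIDATE", "mtdna_haplotype": "unknown"},
        index=pd.Index(new_ids, name="sample_id"),
    )
    samples = pd.concat([parents.samples, hyb_samples])
    calls = np.hstack([parents.calls, hyb_calls])
    m = GenotypeMatrix(calls, parents.loci.copy(), samples)
    m.loci["call_rate"] = m.recomputed_call_rate()
    out_truth = SimTruth(
        locus_category=truth.locus_category.copy(),
        pedigree_class=pd.concat(
            [truth.pedigree_class,
             pd.Series(new_cls, index=hyb_samples.index, name="pedigree_class")]),
        diploid=np.hstack([truth.diploid, hyb_dip]),
    )
    return m, out_truth


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Parental populations plus the configured hybrid pedigree, in one call."""
    parents, truth = simulate_parentals(cfg)
    return simulate_pedigree(parents, truth, cfg)


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def emit_fixture(m: GenotypeMatrix, truth: SimTruth, cfg: SimConfig,
                 out_dir: str | Path) -> dict[str, Path]:
    """Write genotype/sample/truth CSVs plus a config echo, re-readable by dart_io."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cls in ("snp", "pa"):
        rows = (m.loci["marker_class"] == cls).to_numpy()
        if rows.any():
            p = out / f"genotypes_{cls}.csv"
            write_genotype_csv(m.take_loci(rows), p)
            paths[f"genotypes_{cls}"] = p
    paths["samples"] = out / "samples.csv"
    write_sample_csv(m.samples, paths["samples"])
    paths["truth_loci"] = out / "truth_loci.csv"
    truth.locus_category.to_frame().reset_index().to_csv(paths["truth_loci"], index=False)
    paths["truth_samples"] = out / "truth_samples.csv"
    truth.pedigree_class.to_frame().reset_index().to_csv(paths["truth_samples"], index=False)
    paths["config"] = out / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    return paths


def load_fixture(fixture_dir: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read back an emitted fixture (SNP and PA parts combined, samples attached)."""
    d = Path(fixture_dir)
    parts = []
    for cls in ("snp", "pa"):
        p = d / f"genotypes_{cls}.csv"
        if p.exists():
            parts.append(read_genotype_csv(p, cls))
    if not parts:
        raise FileNotFoundError(f"no genotype CSVs under {d}")
    if len(parts) == 2:
        calls = np.vstack([parts[0].calls, parts[1].calls])
        loci = pd.concat([parts[0].loci, parts[1].loci])
        m = GenotypeMatrix(calls, loci, parts[0].samples)
    else:
        m = parts[0]
    samples = read_sample_csv(d / "samples.csv")
    return attach_sample_metadata(m, samples), samples


def replay_config(fixture_dir: str | Path) -> SimConfig:
    with open(Path(fixture_dir) / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    return SimConfig(**raw)
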