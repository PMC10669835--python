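"""Diagnostic-allele scoring and combined-evidence hybrid classification.

Each individual is scored by allele-copy counting over a diagnostic panel:
at a called SNP panel locus the individual contributes two allele copies
split between the species (homozygote for the diagnostic state → 2 to that
species; heterozygote → 1 to each; opposite homozygote → 2 to the other
species); a PA locus contributes one copy by presence state.  The fractions
propA and propB always sum to 1 over the contributed copies, matching the
convention in which a first-generation hybrid reads 50%/50% and each
backcross generation halves the minor-parent share.

Classification then walks a fixed decision sequence — purity, F1/F2 band
with panel heterozygosity separating F1 (≈1) from F2 (≈0.5), backcross
generation from the expected halving (g = round(−log₂ f) − 1) — and checks
the nuclear verdict against optional corroborating evidence (an external
admixture q, an mtDNA D-loop haplotype, PCR marker band patterns).
Conflicting evidence demotes the call to ``unresolved`` with the conflict
recorded; the mtDNA label never overrides the nuclear verdict, it annotates
the maternal lineage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dart_io import MISSING, GenotypeMatrix
from .panel import DiagnosticPanel

#: PCR marker → target species for the default three-marker assay
#: (two focal-species markers, one other-species marker).
DEFAULT_MARKER_TABLE = {"CST09": "A", "CPT08": "A", "CST01": "B"}

BAND_VERDICTS = ("consistent_pureA", "consistent_pureB", "hybrid_banding",
                 "inconclusive")


@dataclass
class DecisionConfig:
    """Thresholds of the combined decision scheme.

    ``purity_epsilon`` — largest foreign diagnostic-allele fraction still
    called pure (default 0: any foreign copy blocks purity).
    ``q_noise_threshold`` — background-noise level for the external
    admixture proportion (default 0.05).
    ``f1_band`` — minor-fraction interval read as first/second-generation
    hybrid (default [0.40, 0.60]).
    ``f1_het_min`` — minimum heterozygosity at reciprocally fixed panel loci
    to call F1 rather than F2 (Mendelian expectation: F1 = 1, F2 = 0.5).
    """

    purity_epsilon: float = 0.0
    q_noise_threshold: float = 0.05
    f1_band: tuple[float, float] = (0.40, 0.60)
    f1_het_min: float = 0.85

    def validate(self) -> None:
        lo, hi = self.f1_band
        if not (0 <= lo < hi <= 1):
            raise ValueError("f1_band must be an ordered sub-interval of [0,1]")
        if not 0 <= self.purity_epsilon < lo:
            raise ValueError("purity_epsilon must lie below the F1 band")


@dataclass
class HybridReport:
    """Per-individual scores, assigned class and evidence trail."""

    table: pd.DataFrame                      # indexed by sample_id
    evidence: dict[str, list[tuple[str, str, str]]]

    def to_csv(self, path) -> None:
        self.table.reset_index().to_csv(path, index=False)

    def text_block(self, sample_id: str) -> str:
        row = self.table.loc[sample_id]
        lines = [
            f"sample {sample_id}: class {row['assigned_class']}",
            f"  panel loci called: {row['n_panel_loci_called']}",
            f"  propA {row['propA']:.4f}  propB {row['propB']:.4f}  "
            f"het_panel {row['het_panel']:.4f}",
        ]
        for criterion, inp, verdict in self.evidence[sample_id]:
            lines.append(f"  [{criterion}] {inp} -> {verdict}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def diagnostic_proportions(
    m: GenotypeMatrix, panel: DiagnosticPanel
) -> pd.DataFrame:
    """Allele-copy fractions per sample over called panel loci.

    Returns a frame with propA, propB (summing to 1 where any panel locus is
    called, else NaN with ``n_panel_loci_called`` 0), het_panel (heterozygote
    fraction at reciprocally fixed SNP panel loci) and n_panel_loci_called.
    """
    if len(panel) == 0:
        raise ValueError("diagnostic panel is empty")
    entries = panel.entries
    loc_idx = np.asarray([m.locus_ids.get_loc(l) for l in entries.index])
    calls = m.calls[loc_idx]
    species = entries["species"].to_numpy()
    state = entries["state"].to_numpy()
    mc = entries["marker_class"].to_numpy()
    is_snp = mc == "snp"
    recip_snp = is_snp & (entries["status"].to_numpy() == "fixed_opposite")

    rows = []
    for j, sid in enumerate(m.sample_ids):
        g = calls[:, j]
        called = g != MISSING
        n_called = int(called.sum())
        copies = {"A": 0.0, "B": 0.0}
        # SNP loci: dosage of the diagnostic allele out of 2 copies
        snp = called & is_snp
        dos = np.where(state[snp] == 2, g[snp], 2 - g[snp]).astype(float)
        for sp in ("A", "B"):
            sel = species[snp] == sp
            copies[sp] += dos[sel].sum()
            copies["B" if sp == "A" else "A"] += (2 - dos[sel]).sum()
        # PA loci: one copy by presence state
        pa = called & ~is_snp
        match = (g[pa] == state[pa])
        for sp in ("A", "B"):
            sel = species[pa] == sp
            copies[sp] += match[sel].sum()
            copies["B" if sp == "A" else "A"] += (~match[sel]).sum()
        total = copies["A"] + copies["B"]
        rc = called & recip_snp
        het = float((g[rc] == 1).mean()) if rc.sum() else np.nan
        rows.append({
            "sample_id": sid,
            "propA": copies["A"] / total if total else np.nan,
            "propB": copies["B"] / total if total else np.nan,
            "het_panel": het,
            "n_panel_loci_called": n_called,
        })
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# PCR band patterns
# ---------------------------------------------------------------------------

def band_pattern_check(
    band_pattern: Mapping[str, str],
    marker_table: Mapping[str, str] | None = None,
) -> str:
    """Classify a PCR band pattern against the marker → species table.

    Any A-species and any B-species marker banded together → hybrid
    banding; bands from only one species's markers → consistent with that
    pure species; no bands at all → inconclusive (the recommendation is then
    genome-wide SNP confirmation, since primer-site variation cannot be
    excluded).
    """
    table = DEFAULT_MARKER_TABLE if marker_table is None else marker_table
    present_a = present_b = False
    for marker, status in band_pattern.items():
        if marker not in table:
            raise ValueError(f"unknown marker {marker!r}")
        if status not in ("present", "absent"):
            raise ValueError(f"band status must be present/absent, got {status!r}")
        if status == "present":
            if table[marker] == "A":
                present_a = True
            else:
                present_b = True
    if present_a and present_b:
        return "hybrid_banding"
    if present_a:
        return "consistent_pureA"
    if present_b:
        return "consistent_pureB"
    return "inconclusive"


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def backcross_generation(minor_fraction: float) -> int:
    """Generation estimate from the expected halving of the minor-parent
    share: 0.25 → BC1, 0.125 → BC2, ...  A coarse point estimate, reported
    with low confidence beyond generation 2."""
    if not 0 < minor_fraction < 0.5:
        raise ValueError("minor fraction must lie in (0, 0.5)")
    return max(1, round(-math.log2(minor_fraction)) - 1)


def _snp_verdict(minor: float, het_panel: float, major: str,
                 cfg: DecisionConfig) -> tuple[str, list[tuple[str, str, str]]]:
    ev: list[tuple[str, str, str]] = []
    lo, hi = cfg.f1_band
    if minor <= cfg.purity_epsilon:
        ev.append(("snp_proportions", f"minor={minor:.4g}", f"pure{major}"))
        return f"pure{major}", ev
    if lo <= minor <= hi:
        if not np.isnan(het_panel) and het_panel >= cfg.f1_het_min:
            ev.append(("snp_proportions",
                       f"minor={minor:.4g}, het_panel={het_panel:.3f}", "F1"))
            return "F1", ev
        ev.append(("snp_proportions",
                   f"minor={minor:.4g}, het_panel={het_panel:.3f}", "F2"))
        return "F2", ev
    if minor < lo:
        g = backcross_generation(minor)
        cls = f"BC{g}_to{major}"
        note = "" if g <= 2 else " (low confidence: generation beyond BC2)"
        ev.append(("snp_proportions", f"minor={minor:.4g}", cls + note))
        return cls, ev
    # minor in (hi, 0.5] cannot occur (minor ≤ 0.5 ≤ hi by config validation)
    ev.append(("snp_proportions", f"minor={minor:.4g}", "unresolved"))
    return "unresolved", ev


def classify(
    m: GenotypeMatrix,
    panel: DiagnosticPanel,
    cfg: DecisionConfig | None = None,
    marker_table: Mapping[str, str] | None = None,
) -> HybridReport:
    """Assign pure/F1/F2/backcross/unresolved status per individual.

    Optional columns of ``m.samples`` feed the evidence trail:
    ``external_q`` (major-cluster membership from an external admixture
    model), ``mtdna_haplotype``, and ``band_<marker>`` columns with
    present/absent states.
    """
    cfg = cfg or DecisionConfig()
    cfg.validate()
    props = diagnostic_proportions(m, panel)
    band_cols = [c for c in m.samples.columns if c.startswith("band_")]

    classes, evidence = [], {}
    for sid, row in props.iterrows():
        ev: list[tuple[str, str, str]] = []
        if row["n_panel_loci_called"] == 0:
            classes.append("unresolved")
            evidence[sid] = [("snp_proportions", "no panel loci called", "unresolved")]
            continue
        pa, pb = row["propA"], row["propB"]
        minor = min(pa, pb)
        major = "A" if pa >= pb else "B"
        verdict, ev = _snp_verdict(minor, row["het_panel"], major, cfg)

        meta = m.samples.loc[sid]
        conflict = False

        q = meta.get("external_q", np.nan)
        if pd.notna(q):
            q_minor = min(float(q), 1 - float(q))
            if verdict.startswith("pure") and q_minor > cfg.q_noise_threshold:
                ev.append(("external_q", f"q={q:.3g}",
                           "conflict: admixture above noise for a pure call"))
                conflict = True
            elif verdict in ("F1", "F2") and q_minor <= cfg.q_noise_threshold:
                ev.append(("external_q", f"q={q:.3g}",
                           "conflict: no admixture signal for an F1/F2 call"))
                conflict = True
            else:
                ev.append(("external_q", f"q={q:.3g}", "consistent"))

        mt = meta.get("mtdna_haplotype", None)
        if isinstance(mt, str) and mt != "unknown":
            ev.append(("mtdna_haplotype", mt,
                       f"maternal lineage {mt} (annotation only)"))

        bands = {c[len("band_"):]: meta[c] for c in band_cols if pd.notna(meta[c])}
        if bands:
            bv = band_pattern_check(bands, marker_table)
            implied = {"consistent_pureA": "pureA", "consistent_pureB": "pureB"}
            if bv == "inconclusive":
                ev.append(("band_pattern", str(bands),
                           "inconclusive: recommend genome-wide SNP confirmation"))
            elif bv == "hybrid_banding" and verdict.startswith("pure"):
                ev.append(("band_pattern", str(bands),
                           "conflict: hybrid banding for a pure call"))
                conflict = True
            elif bv in implied and verdict.startswith("pure") and implied[bv] != verdict:
                ev.append(("band_pattern", str(bands),
                           f"conflict: {bv} against {verdict}"))
                conflict = True
            else:
                ev.append(("band_pattern", str(bands), bv))

        if conflict:
            ev.append(("decision", "evidence conflict", "unresolved"))
            verdict = "unresolved"
        classes.append(verdict)
        evidence[sid] = ev

    table = props.copy()
    table["assigned_class"] = classes
    return HybridReport(table=table, evidence=evidence)
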