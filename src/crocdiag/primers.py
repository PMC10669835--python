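"""Screening of diagnostic loci for PCR-marker suitability.

A candidate passes when its flanking sequence around the SNP position
satisfies four criteria: (a) no repeated sequence (by default a homopolymer
run of ≥ 6 bases or a di-/trinucleotide tandem of ≥ 4 units — a motif rule
standing in for primer-design repeat screens, thresholds configurable);
(b) no catalogued SNP inside either flank; (c) one of the locus's two
alleles matches the reference base at the position; (d) both flanks at
least 50 bp.  Primer design itself (melting temperatures, PCR programs) is
out of scope — the module stops at candidate eligibility.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from .dart_io import GenotypeMatrix
from .panel import DiagnosticPanel

DEFAULT_FLANK_LEN = 60
MIN_FLANK = 50


def read_reference(path: str | Path) -> dict[str, str]:
    """Load a FASTA reference as contig → uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def extract_flanks(
    reference: Mapping[str, str], contig: str, position: int,
    flank_len: int = DEFAULT_FLANK_LEN,
) -> tuple[str, str]:
    """Up to ``flank_len`` bases either side of a 1-based SNP position,
    excluding the SNP base itself; truncated at contig edges."""
    if contig not in reference:
        raise KeyError(f"contig {contig!r} not present in reference")
    seq = reference[contig]
    if not 1 <= position <= len(seq):
        raise ValueError(
            f"position {position} outside contig {contig!r} (length {len(seq)})")
    left = seq[max(0, position - 1 - flank_len):position - 1]
    right = seq[position:position + flank_len]
    return left, right


def has_repeat(seq: str, homopolymer_min: int = 6, tandem_min_units: int = 4) -> bool:
    """Motif-rule repeat detection: homopolymer runs and short tandems."""
    if re.search(r"(.)\1{%d,}" % (homopolymer_min - 1), seq):
        return True
    for unit in (2, 3):
        pat = r"(.{%d})\1{%d,}" % (unit, tandem_min_units - 1)
        for mm in re.finditer(pat, seq):
            if len(set(mm.group(1))) > 1:   # pure homopolymers handled above
                return True
    return False


@dataclass
class FlankReport:
    locus_id: str
    left_flank: str
    right_flank: str
    criteria: dict[str, bool]

    @property
    def left_len(self) -> int:
        return len(self.left_flank)

    @property
    def right_len(self) -> int:
        return len(self.right_flank)

    @property
    def overall(self) -> bool:
        return all(self.criteria.values())


def screen_candidate(
    locus_id: str,
    contig: str,
    position: int,
    ref_allele: str,
    alt_allele: str,
    reference: Mapping[str, str],
    snp_catalogue: pd.DataFrame | None = None,
    flank_len: int = DEFAULT_FLANK_LEN,
    min_flank: int = MIN_FLANK,
    homopolymer_min: int = 6,
    tandem_min_units: int = 4,
) -> FlankReport:
    """Evaluate the four flank criteria for one locus.

    ``snp_catalogue`` lists known variant positions as columns ``contig``
    and 1-based ``position`` on the same coordinate system as the
    reference; the screened position itself does not count against (b).
    """
    left, right = extract_flanks(reference, contig, position, flank_len)
    ref_base = reference[contig][position - 1]

    snp_free = True
    if snp_catalogue is not None:
        if not {"contig", "position"} <= set(snp_catalogue.columns):
            raise ValueError(
                "snp_catalogue must have 'contig' and 'position' columns "
                "(1-based, reference coordinates)")
        on_contig = snp_catalogue[snp_catalogue["contig"] == contig]
        pos = on_contig["position"].astype(int)
        in_left = (pos >= position - len(left)) & (pos <= position - 1)
        in_right = (pos >= position + 1) & (pos <= position + len(right))
        snp_free = not bool((in_left | in_right).any())

    criteria = {
        "no_repeats": not (has_repeat(left, homopolymer_min, tandem_min_units)
                           or has_repeat(right, homopolymer_min, tandem_min_units)),
        "snp_free_flank": snp_free,
        "allele_matches_reference": ref_base in (ref_allele.upper(),
                                                 alt_allele.upper()),
        "flank_length_ok": len(left) >= min_flank and len(right) >= min_flank,
    }
    return FlankReport(locus_id=locus_id, left_flank=left, right_flank=right,
                       criteria=criteria)


def screen_panel(
    m: GenotypeMatrix,
    panel: DiagnosticPanel,
    reference: Mapping[str, str],
    snp_catalogue: pd.DataFrame | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Screen every panel locus; returns one row per locus with the four
    criteria and the overall verdict."""
    rows = []
    for locus_id in panel.entries.index:
        info = m.loci.loc[locus_id]
        rep = screen_candidate(
            locus_id, info["contig"], int(info["position"]),
            info["ref"], info["alt"], reference, snp_catalogue, **kwargs)
        rows.append({
            "locus_id": locus_id,
            "left_len": rep.left_len, "right_len": rep.right_len,
            **rep.criteria, "overall": rep.overall,
        })
    return pd.DataFrame(rows).set_index("locus_id")


def synthesize_reference(
    m: GenotypeMatrix, seed: int = 0, pad: int = 80
) -> dict[str, str]:
    """Synthetic reference sequences consistent with the locus metadata.

    Random sequence is generated per contig (deterministically from
    ``seed``) with each locus's reference allele planted at its 1-based
    position.  Useful for exercising the primer screen on simulated data.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    bases = "ACGT"
    out: dict[str, str] = {}
    for contig, group in m.loci.groupby("contig", sort=False):
        length = int(group["position"].max()) + pad
        seq = list(rng.choice(list(bases), size=length))
        for locus_id, row in group.iterrows():
            seq[int(row["position"]) - 1] = row["ref"]
        out[str(contig)] = "".join(seq)
    return out


def write_reference(reference: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, seq in reference.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
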