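"""Variant sequence panels and mutation bookkeeping.

Humanization panels are positionally aligned by construction (framework
substitutions, no indels), so differences to the template are read off
position by position; a length mismatch is an error, never an alignment
trigger.  Mutations are named in the conventional from-position-to form
(e.g. ``T98R``), using the author/config-supplied numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Region label order used for sanity checks.
REGION_LABELS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")


@dataclass
class ChainSequence:
    variant_id: str
    chain: str                    # "H" or "L"
    residues: str                 # one-letter codes, uppercase
    numbering: tuple = None       # author numbers, same length

    def __post_init__(self):
        self.residues = self.residues.upper()
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"{self.variant_id}/{self.chain}: non-amino-acid "
                f"characters {sorted(bad)}"
            )
        if self.chain not in ("H", "L"):
            raise ValueError(f"chain must be H or L, got {self.chain!r}")
        if self.numbering is None:
            self.numbering = tuple(range(1, len(self.residues) + 1))
        else:
            self.numbering = tuple(int(x) for x in self.numbering)
        if len(self.numbering) != len(self.residues):
            raise ValueError("numbering and sequence lengths differ")


@dataclass(frozen=True)
class MutationAnnotation:
    position: int                 # author number
    from_aa: str                  # template residue
    to_aa: str                    # variant residue
    region: str                   # FR/CDR label from configured ranges

    def __post_init__(self):
        if self.from_aa == self.to_aa:
            raise ValueError("mutation with identical from/to residue")

    @property
    def name(self) -> str:
        return f"{self.from_aa}{self.position}{self.to_aa}"


def read_fasta_panel(path) -> list:
    """Parse a FASTA panel; headers encode ``variant_id|chain``.

    A header without an explicit chain defaults to H.  Lowercase sequence
    is uppercased; non-amino-acid characters are an error naming the
    record.
    """
    path = Path(path)
    sequences = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        vid = parts[0]
        chain = parts[1].upper() if len(parts) > 1 else "H"
        try:
            sequences.append(ChainSequence(variant_id=vid, chain=chain,
                                           residues=str(rec.seq)))
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return sequences


def _validate_region_ranges(region_ranges: dict, numbering) -> None:
    """Configured ranges must tile the numbering without overlap."""
    covered = {}
    for label, (lo, hi) in region_ranges.items():
        for p in range(int(lo), int(hi) + 1):
            if p in covered:
                raise ValueError(
                    f"regions {covered[p]} and {label} overlap at position {p}"
                )
            covered[p] = label
    missing = [p for p in numbering if p not in covered]
    if missing:
        raise ValueError(f"positions {missing[:10]} not covered by any "
                         "configured region range")


def region_of(position: int, region_ranges: dict) -> str:
    for label, (lo, hi) in region_ranges.items():
        if int(lo) <= position <= int(hi):
            return label
    return "?"


def diff_to_template(variant: ChainSequence, template: ChainSequence,
                     region_ranges: dict) -> list:
    """Mutations of a variant relative to the template, region-labeled.

    CDR-region differences are reported but warned about, because the CDRs
    are expected to stay constant across a humanization panel.
    """
    if len(variant.residues) != len(template.residues):
        raise ValueError(
            f"{variant.variant_id}/{variant.chain}: length "
            f"{len(variant.residues)} differs from template "
            f"{len(template.residues)} (panels must be positionally aligned)"
        )
    if variant.numbering != template.numbering:
        raise ValueError("variant and template numbering differ")
    _validate_region_ranges(region_ranges, template.numbering)
    annotations = []
    for pos, t_aa, v_aa in zip(template.numbering, template.residues,
                               variant.residues):
        if t_aa == v_aa:
            continue
        label = region_of(pos, region_ranges)
        ann = MutationAnnotation(position=pos, from_aa=t_aa, to_aa=v_aa,
                                 region=label)
        if label.startswith("CDR"):
            warnings.warn(
                f"{variant.variant_id}: mutation {ann.name} lies in "
                f"{label}; CDRs are expected to be conserved",
                stacklevel=2,
            )
        annotations.append(ann)
    return annotations


def check_cdr_conserved(panel, template: ChainSequence,
                        region_ranges: dict) -> list:
    """Variant ids with any CDR-region difference from the template.

    A hit is a reported fact (a BM10-style deliberate CDR mutant), not an
    error.
    """
    violators = []
    for seq in panel:
        if seq.chain != template.chain:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anns = diff_to_template(seq, template, region_ranges)
        if any(a.region.startswith("CDR") for a in anns):
            violators.append(seq.variant_id)
    return violators


def write_mutation_table(panel, template, region_ranges, path) -> None:
    """Delimited mutation report: variant, chain, mutation, region."""
    with open(path, "w") as fh:
        fh.write("variant\tchain\tmutation\tregion\n")
        for seq in panel:
            if seq.chain != template.chain or seq.variant_id == template.variant_id:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                anns = diff_to_template(seq, template, region_ranges)
            for a in anns:
                fh.write(f"{seq.variant_id}\t{seq.chain}\t{a.name}\t{a.region}\n")
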