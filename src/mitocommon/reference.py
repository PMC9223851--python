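"""Reference genome access (rCRS coordinates, 1-based, circular)."""

from __future__ import annotations

import warnings
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

from .nomenclature import (
    DELETION,
    INSERTION,
    MT_LENGTH,
    Haplotype,
    NomenclatureError,
    Variant,
)

_BUNDLED = "rcrs_synthetic.fasta"


class ReferenceGenome:
    """A single circular mtDNA reference sequence with 1-based lookups."""

    def __init__(self, sequence: str, identifier: str = "rCRS"):
        sequence = sequence.upper()
        if len(sequence) != MT_LENGTH:
            raise ValueError(
                f"mtDNA reference must have {MT_LENGTH} bases, "
                f"got {len(sequence)}"
            )
        self.sequence = sequence
        self.identifier = identifier

    def base_at(self, position: int) -> str:
        if not 1 <= position <= MT_LENGTH:
            raise NomenclatureError(f"np {position} outside 1..{MT_LENGTH}")
        return self.sequence[position - 1]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(f"{path}: expected a single FASTA record")
        return cls(str(records[0].seq), identifier=records[0].id)

    def annotate(self, v: Variant) -> Variant:
        """Return the variant with its reference base filled in."""
        if v.kind == INSERTION:
            return v
        ref = self.base_at(v.position)
        if v.reference_base and v.reference_base != ref:
            warnings.warn(
                f"variant at np {v.position}: stated reference base "
                f"{v.reference_base!r} differs from loaded reference {ref!r}",
                stacklevel=2,
            )
        if v.reference_base == ref:
            return v
        return Variant(
            position=v.position,
            insertion_index=v.insertion_index,
            kind=v.kind,
            observed=v.observed,
            heteroplasmic=v.heteroplasmic,
            reference_base=ref,
        )

    def validate_haplotype(self, h: Haplotype) -> list[str]:
        """Soft checks against the reference; returns warning strings.

        A substitution whose observed symbol equals (or, for a PHP, excludes)
        the reference base is suspicious but tolerated — tokens in the wild
        omit reference bases, so mismatches warn rather than fail.
        """
        notes = []
        for v in h.variants:
            if v.kind == DELETION or v.kind == INSERTION:
                continue
            ref = self.base_at(v.position)
            if not v.heteroplasmic and v.observed == ref:
                notes.append(
                    f"{h.sample_id}: np {v.position}{v.observed} equals the "
                    "reference base"
                )
            if v.heteroplasmic and ref not in v.components:
                notes.append(
                    f"{h.sample_id}: PHP {v.position}{v.observed} excludes "
                    f"the reference base {ref}"
                )
        return notes


@lru_cache(maxsize=1)
def bundled_reference() -> ReferenceGenome:
    """The bundled synthetic rCRS stand-in (see :mod:`mitocommon._synthetic`)."""
    path = resources.files("mitocommon.data").joinpath(_BUNDLED)
    with resources.as_file(path) as p:
        return ReferenceGenome.from_fasta(p)


def get_reference(ref: Optional[ReferenceGenome] = None) -> ReferenceGenome:
    return ref if ref is not None else bundled_reference()
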