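"""Domain types: primers and template records."""

from __future__ import annotations

from dataclasses import dataclass, field

from . import iupac

__all__ = ["Primer", "TemplateRecord", "ValidationError"]


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Primer:
    """A named, oriented, possibly degenerate oligonucleotide.

    ``sequence`` is written 5'->3' in the primer's own orientation.  A
    reverse primer anneals to the plus strand's complement; its
    plus-strand footprint sequence is its reverse complement.
    ``intended_footprint`` is the closed interval of the annealing site
    in E. coli 16S numbering (1-1542), when the design specifies one.
    """

    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"
    intended_footprint: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"primer {self.name!r}: empty sequence")
        object.__setattr__(self, "sequence", iupac.normalize(self.sequence))
        if self.orientation not in ("forward", "reverse"):
            raise ValidationError(
                f"primer {self.name!r}: orientation must be "
                f"'forward' or 'reverse', got {self.orientation!r}"
            )
        if self.intended_footprint is not None:
            lo, hi = self.intended_footprint
            if not (1 <= lo <= hi <= 1542):
                raise ValidationError(
                    f"primer {self.name!r}: intended footprint {lo}-{hi} "
                    "outside 1-1542"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def plus_strand_sequence(self) -> str:
        """The sequence this primer imposes on the plus strand, 5'->3'."""
        if self.orientation == "reverse":
            return iupac.revcomp(self.sequence)
        return self.sequence


@dataclass
class TemplateRecord:
    """One 16S rRNA gene sequence with its taxonomy label.

    ``sequence`` is the plus strand, 5'->3' in gene orientation, possibly
    with ~50-nt flanks beyond the gene ends (``has_flanks``).
    """

    id: str
    sequence: str
    taxon_phylum: str = "unclassified"
    taxon_class: str = ""
    has_flanks: bool = False

    def __post_init__(self) -> None:
        self.sequence = iupac.normalize(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)
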