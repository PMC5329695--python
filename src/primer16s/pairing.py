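"""Auditing primers against base-paired variable sites of the 16S
central pseudoknot, and predicting primer-templated amplicon artifacts.

Helix h2 of the central pseudoknot pairs nucleotides 17-19 with 918-916
(E. coli numbering). Position 19 covaries across bacteria (19A pairing
916U in gammaproteobacteria-like sequences, 19C pairing 916G in
betaproteobacteria-like ones), so a primer whose footprint covers
position 19 can overwrite the template's base and create a non-native
19-916 combination in the amplicon. Functional-complementation assays
established which combinations support ribosome function; that rule
table is encoded here exactly as measured — the native A-U and C-G
pairs and the non-native A-G pair are functional, the non-native C-U
pair is defective, and every untested combination is classified
unknown, never extrapolated from RNA chemistry.

Position 1527 is a lone variable site (C or U) under the 3'-terminal
primer footprints; it is audited for mismatch potential but carries no
functionality rule.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from . import iupac
from .anchor import CoordinateMap, MatchResult, anchor_primer
from .core import Primer, TemplateRecord, ValidationError
from .coverage import CompositionProfile, VariableSiteReport, variable_sites_in_footprint

__all__ = [
    "PairClass",
    "PairedSiteRegistry",
    "PairState",
    "AmpliconPrediction",
    "AuditVerdict",
    "classify_pair",
    "pair_geometry",
    "template_pair_state",
    "predict_amplicon",
    "audit_primer",
]

ABSENT = None  # marker for a base at an unspanned/gapped position


class PairClass(enum.Enum):
    """Functionality class of a 19-916 base-pair combination."""

    NATIVE_FUNCTIONAL = "native_functional"
    NONNATIVE_FUNCTIONAL = "nonnative_functional"
    NONNATIVE_DEFECTIVE = "nonnative_defective"
    ABSENT = "absent"
    UNKNOWN = "unknown"


# experimentally established combinations, (base19, base916) in DNA alphabet
_RULE_TABLE = {
    ("A", "T"): PairClass.NATIVE_FUNCTIONAL,     # gamma-like 19A-916U
    ("C", "G"): PairClass.NATIVE_FUNCTIONAL,     # beta-like 19C-916G
    ("A", "G"): PairClass.NONNATIVE_FUNCTIONAL,  # primer-creatable, tolerated
    ("C", "T"): PairClass.NONNATIVE_DEFECTIVE,   # primer-creatable, defective
}


@dataclass(frozen=True)
class PairedSiteRegistry:
    """Annotated base-paired positions plus lone variable sites.

    Defaults describe helix h2 (17-918, 18-917, 19-916) with 19-916 as
    the functionally assayed focus pair, and 1527 as a lone variable
    site with no pairing partner.
    """

    pairs: tuple[tuple[int, int], ...] = ((17, 918), (18, 917), (19, 916))
    lone_variable_sites: tuple[int, ...] = (1527,)
    focus_pair: tuple[int, int] = (19, 916)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for a, b in self.pairs:
            if a >= b:
                raise ValidationError(f"pair ({a}, {b}): expected pos_a < pos_b")
            for p in (a, b):
                if p in seen:
                    raise ValidationError(f"position {p} appears twice in registry")
                seen.add(p)
        for p in self.lone_variable_sites:
            if p in seen:
                raise ValidationError(f"position {p} appears twice in registry")
            seen.add(p)

    def partner_of(self, pos: int) -> int | None:
        for a, b in self.pairs:
            if pos == a:
                return b
            if pos == b:
                return a
        return None

    @property
    def all_positions(self) -> frozenset[int]:
        return frozenset(p for ab in self.pairs for p in ab) | frozenset(
            self.lone_variable_sites)


def classify_pair(base_19: str | None, base_916: str | None) -> PairClass:
    """Classify a 19-916 combination by the assayed functionality rules.

    Accepts DNA or RNA alphabet (U treated as T); ``None`` marks an
    absent base (unspanned or gapped position). Ambiguous IUPAC codes
    are rejected: expand them and classify each concrete combination.
    """
    bases = []
    for b in (base_19, base_916):
        if b is ABSENT or b == "-":
            return PairClass.ABSENT
        b = b.upper().replace("U", "T")
        if b not in "ACGT":
            if b in iupac.IUPAC_CODES:
                raise ValidationError(
                    f"ambiguous base {b!r}: expand the IUPAC code and "
                    "classify each concrete base separately")
            raise iupac.InvalidNucleotideError(f"invalid base {b!r}")
        bases.append(b)
    return _RULE_TABLE.get((bases[0], bases[1]), PairClass.UNKNOWN)


def pair_geometry(base_a: str | None, base_b: str | None) -> str:
    """Watson-Crick / wobble / mispair annotation (T treated as U)."""
    if base_a is ABSENT or base_b is ABSENT:
        return "absent"
    pair = frozenset((base_a.replace("U", "T"), base_b.replace("U", "T")))
    if pair in (frozenset("AT"), frozenset("CG")):
        return "watson_crick"
    if pair == frozenset("GT"):
        return "wobble"
    return "mispair"


@dataclass
class PairState:
    """One registry pair read off a template."""

    pair: tuple[int, int]
    base_a: str | None
    base_b: str | None
    geometry: str
    pair_class: PairClass | None  # functionality class; focus pair only


def template_pair_state(template: TemplateRecord | str,
                        cmap: CoordinateMap,
                        registry: PairedSiteRegistry = PairedSiteRegistry(),
                        ) -> list[PairState]:
    """Read and annotate every registry pair on one template.

    The focus pair gets a functionality class from :func:`classify_pair`;
    other pairs carry geometry annotation only, since only the focus
    pair was functionally assayed.
    """
    seq = template.sequence if isinstance(template, TemplateRecord) else template
    states = []
    for a, b in registry.pairs:
        ba = cmap.base_at(seq, a)
        bb = cmap.base_at(seq, b)
        cls = None
        if (a, b) == registry.focus_pair:
            try:
                cls = classify_pair(ba, bb)
            except ValidationError:
                cls = PairClass.UNKNOWN  # ambiguous template base
        states.append(PairState((a, b), ba, bb, pair_geometry(ba, bb), cls))
    return states


@dataclass
class Substitution:
    """A primer-templated base change fixed into an amplicon."""

    ecoli_pos: int | None
    template_pos: int
    template_base: str
    imposed_base: str
    ambiguous: bool = False  # imposed base chosen among a degenerate expansion


@dataclass
class AmpliconPrediction:
    template_id: str
    amplifiable: bool
    fwd: MatchResult | None = None
    rev: MatchResult | None = None
    substitutions: list[Substitution] = field(default_factory=list)
    pair_states_before: list[PairState] = field(default_factory=list)
    pair_states_after: list[PairState] = field(default_factory=list)
    risk_flag: str = "none"  # none | artifact_functional | artifact_defective | unknown_pair
    amplicon_span_template: tuple[int, int] | None = None
    amplicon_sequence: str | None = None


def _footprint_substitutions(primer: Primer, match: MatchResult,
                             seq: str, cmap: CoordinateMap) -> list[Substitution]:
    probe = primer.plus_strand_sequence
    start = match.footprint_template[0] - 1
    subs = []
    for i, pbase in enumerate(probe):
        tpos = start + i
        tbase = seq[tpos]
        if iupac.iupac_match(pbase, tbase):
            continue  # degenerate/matching position adopts the template base
        exp = sorted(iupac.expand(pbase))
        subs.append(Substitution(
            ecoli_pos=cmap.to_ecoli(tpos + 1),
            template_pos=tpos + 1,
            template_base=tbase,
            imposed_base=exp[0],
            ambiguous=len(exp) > 1,
        ))
    return subs


def predict_amplicon(template: TemplateRecord,
                     fwd: Primer,
                     rev: Primer,
                     cmap: CoordinateMap,
                     registry: PairedSiteRegistry = PairedSiteRegistry(),
                     window: int = 100) -> AmpliconPrediction:
    """Predict the amplicon a primer pair produces from one template.

    The amplicon is the template span between the two footprints with
    footprint positions overwritten by the primer-imposed bases; the
    registry pair states are re-read from the mutated sequence and the
    focus pair is re-classified. ``risk_flag`` reports whether the
    amplification changed the focus pair into a non-native (functional
    or defective) or untested combination.
    """
    if fwd.orientation != "forward" or rev.orientation != "reverse":
        raise ValidationError("predict_amplicon needs one forward and one reverse primer")
    if not cmap.anchorable:
        return AmpliconPrediction(template.id, amplifiable=False)
    m_fwd = anchor_primer(fwd, template, cmap, window=window)
    m_rev = anchor_primer(rev, template, cmap, window=window)
    if not (m_fwd.anchored and m_rev.anchored):
        return AmpliconPrediction(template.id, amplifiable=False,
                                  fwd=m_fwd, rev=m_rev)

    seq = template.sequence
    subs = (_footprint_substitutions(fwd, m_fwd, seq, cmap)
            + _footprint_substitutions(rev, m_rev, seq, cmap))

    before = template_pair_state(seq, cmap, registry)
    mutated = list(seq)
    for s in subs:
        mutated[s.template_pos - 1] = s.imposed_base
    mutated = "".join(mutated)
    after = template_pair_state(mutated, cmap, registry)

    focus_before = next(s.pair_class for s in before if s.pair == registry.focus_pair)
    focus_after = next(s.pair_class for s in after if s.pair == registry.focus_pair)
    if focus_after == focus_before:
        risk = "none"
    elif focus_after == PairClass.NONNATIVE_DEFECTIVE:
        risk = "artifact_defective"
    elif focus_after == PairClass.NONNATIVE_FUNCTIONAL:
        risk = "artifact_functional"
    else:
        risk = "unknown_pair"

    span = (m_fwd.footprint_template[0], m_rev.footprint_template[1])
    return AmpliconPrediction(
        template_id=template.id,
        amplifiable=True,
        fwd=m_fwd,
        rev=m_rev,
        substitutions=subs,
        pair_states_before=before,
        pair_states_after=after,
        risk_flag=risk,
        amplicon_span_template=span,
        amplicon_sequence=mutated[span[0] - 1: span[1]],
    )


@dataclass
class AuditVerdict:
    primer_name: str
    safe: bool
    offending_positions: list[int]
    report: VariableSiteReport

    @property
    def verdict(self) -> str:
        return "safe" if self.safe else "unsafe"


def audit_primer(primer: Primer,
                 registry: PairedSiteRegistry,
                 profile: CompositionProfile,
                 minor_freq_threshold: float = 0.05) -> AuditVerdict:
    """Is a primer safe for functional cloning on this collection?

    Unsafe iff its footprint overlaps a registry position (a paired-site
    member or lone variable site) that is polymorphic at or above the
    minor-allele threshold in the composition profile.
    """
    report = variable_sites_in_footprint(primer, profile, registry,
                                         minor_freq_threshold)
    offending = [p for p in report.positions if p in registry.all_positions]
    return AuditVerdict(primer.name, safe=not offending,
                        offending_positions=offending, report=report)
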