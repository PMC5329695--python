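"""E. coli-numbering coordinate maps and terminal primer placement.

Positions in 16S rRNA are conventionally reported in *E. coli*
coordinates (1-1542). A ``CoordinateMap`` carries that frame onto an
arbitrary template via pairwise semi-global alignment (free end gaps on
both sequences, so 50-nt flanks and truncations cost nothing), computed
with Biopython's PairwiseAligner over an IUPAC-aware substitution
matrix. Primer placement is gap-free: PCR primers anneal contiguously,
so a primer is slid over the terminal window of the template and scored
by IUPAC mismatch count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from . import iupac
from .core import Primer, TemplateRecord

__all__ = [
    "AlignParams",
    "CoordinateMap",
    "MatchResult",
    "build_coordinate_map",
    "anchor_primer",
]

GAP = None  # template-side gap marker inside CoordinateMap.pairs

ALPHABET = "ACGTRYSWKMBDHVN"


@dataclass(frozen=True)
class AlignParams:
    """Alignment scoring for coordinate mapping (defaults: +2/-3, gap -5/-2)."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    min_template_length: int = 200
    min_identity: float = 0.60
    min_aligned_span: int = 200  # reference columns; rejects spurious short overlaps


@lru_cache(maxsize=8)
def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    mat = substitution_matrices.Array(ALPHABET, dims=2)
    for a in ALPHABET:
        for b in ALPHABET:
            compatible = bool(iupac.expand(a) & iupac.expand(b))
            mat[a, b] = params.match if compatible else params.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    # free end gaps on both sequences: flanks and truncations are unpenalized
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


@dataclass
class CoordinateMap:
    """Mapping between a template and E. coli 16S numbering.

    ``pairs`` lists ``(ecoli_pos, template_pos)`` over the aligned
    reference span, both 1-based; ``template_pos`` is None where the
    template has a deletion relative to the reference. Positions outside
    the aligned span are *absent* (queries return None, never raise).
    """

    template_id: str
    pairs: list[tuple[int, int | None]]
    score: float
    identity: float
    anchorable: bool
    _fwd: dict[int, int | None] = field(repr=False, default_factory=dict)
    _rev: dict[int, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._fwd = {e: t for e, t in self.pairs}
        self._rev = {t: e for e, t in self.pairs if t is not None}

    def to_template(self, ecoli_pos: int) -> int | None:
        """Template position for an E. coli position, or None if gapped/unspanned."""
        return self._fwd.get(ecoli_pos)

    def to_ecoli(self, template_pos: int) -> int | None:
        return self._rev.get(template_pos)

    def base_at(self, template: TemplateRecord | str, ecoli_pos: int) -> str | None:
        """Template base at an E. coli position; None if absent."""
        tpos = self.to_template(ecoli_pos)
        if tpos is None:
            return None
        seq = template.sequence if isinstance(template, TemplateRecord) else template
        return seq[tpos - 1]

    @property
    def ecoli_span(self) -> tuple[int, int] | None:
        if not self.pairs:
            return None
        return self.pairs[0][0], self.pairs[-1][0]


@dataclass
class MatchResult:
    """Best gap-free placement of one primer on one template."""

    template_id: str
    primer_name: str
    anchored: bool
    footprint_template: tuple[int, int] | None = None
    footprint_ecoli: tuple[int, int] | None = None
    n_mismatches: int | None = None
    mismatch_positions: list[int | None] = field(default_factory=list)


def build_coordinate_map(template: TemplateRecord | str,
                         reference: str,
                         params: AlignParams = AlignParams()) -> CoordinateMap:
    """Semi-global alignment of a template to the E. coli reference.

    Templates shorter than ``params.min_template_length`` or aligning
    below ``params.min_identity`` (matched columns over the aligned
    reference span) are flagged unanchorable rather than raising.
    """
    if isinstance(template, str):
        template = TemplateRecord(id="<anonymous>", sequence=template)
    seq = template.sequence
    if len(seq) < params.min_template_length:
        return CoordinateMap(template.id, [], float("-inf"), 0.0, False)

    aln = _aligner(params).align(reference, seq)[0]
    blocks = aln.aligned  # gapless chunks: ((ref_start, ref_end), (tmpl_start, tmpl_end))
    pairs: list[tuple[int, int | None]] = []
    matched = 0
    prev_ref_end = None
    for (rs, re_), (ts, te) in zip(*blocks):
        rs, re_, ts = int(rs), int(re_), int(ts)
        if prev_ref_end is not None:
            for e in range(prev_ref_end + 1, rs + 1):  # deletion in template
                pairs.append((e, None))
        for k in range(re_ - rs):
            e, t = rs + k + 1, ts + k + 1
            pairs.append((e, t))
            if iupac.iupac_match(reference[e - 1], seq[t - 1]):
                matched += 1
        prev_ref_end = re_
    # identity over all aligned columns: matches + mismatches + internal gaps
    tpos = [t for _, t in pairs if t is not None]
    n_insertions = (tpos[-1] - tpos[0] + 1 - len(tpos)) if tpos else 0
    n_columns = len(pairs) + n_insertions
    identity = matched / n_columns if n_columns else 0.0
    span = len(pairs)
    anchorable = (span >= min(params.min_aligned_span, len(reference))
                  and identity >= params.min_identity)
    return CoordinateMap(template.id, pairs, float(aln.score), identity, anchorable)


def _count_mismatches(probe: str, seq: str, start: int) -> tuple[int, list[int]]:
    n = 0
    offsets = []
    for i, p in enumerate(probe):
        if not iupac.iupac_match(p, seq[start + i]):
            n += 1
            offsets.append(i)
    return n, offsets


def anchor_primer(primer: Primer,
                  template: TemplateRecord,
                  cmap: CoordinateMap,
                  window: int = 100) -> MatchResult:
    """Best gap-free placement of ``primer`` within the terminal window.

    Forward primers are searched at the 5' terminus (start within the
    first ``window`` positions), reverse primers at the 3' terminus
    (footprint end within the last ``window``); reverse primers are
    matched as their reverse complement against the plus strand. The
    minimum-mismatch placement wins; ties break toward the placement
    whose E. coli footprint equals the primer's intended footprint, then
    toward the terminus.
    """
    seq = template.sequence
    probe = primer.plus_strand_sequence
    k = len(probe)
    if len(seq) < k:
        return MatchResult(template.id, primer.name, anchored=False)

    last_start = len(seq) - k
    if primer.orientation == "forward":
        starts = range(0, min(window, last_start + 1))
        terminus_order = lambda s: s
    else:
        starts = range(max(0, last_start - window + 1), last_start + 1)
        terminus_order = lambda s: -s
    starts = list(starts)
    if not starts:
        return MatchResult(template.id, primer.name, anchored=False)

    scored = []
    for s in starts:
        n, offsets = _count_mismatches(probe, seq, s)
        scored.append((s, n, offsets))

    best_n = min(n for _, n, _ in scored)
    candidates = [(s, offsets) for s, n, offsets in scored if n == best_n]

    def ecoli_footprint(s: int) -> tuple[int, int] | None:
        lo, hi = cmap.to_ecoli(s + 1), cmap.to_ecoli(s + k)
        return (lo, hi) if lo is not None and hi is not None else None

    def rank(cand):
        s, _ = cand
        intended = (primer.intended_footprint is not None
                    and ecoli_footprint(s) == primer.intended_footprint)
        return (0 if intended else 1, terminus_order(s))

    start, offsets = min(candidates, key=rank)
    fp_t = (start + 1, start + k)
    return MatchResult(
        template_id=template.id,
        primer_name=primer.name,
        anchored=True,
        footprint_template=fp_t,
        footprint_ecoli=ecoli_footprint(start),
        n_mismatches=best_n,
        mismatch_positions=[cmap.to_ecoli(start + 1 + i) for i in offsets],
    )
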