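"""Tabulation of clone libraries by taxon origin and 19-916 pattern.

Produces the contingency summaries used to compare primer sets: per
library, counts and integer percentages of clone origins (taxon class)
and of the four 19-916 base-pair patterns (A-G, A-U, C-G, C-U; U is the
display form of internal T). Percentages are always recomputed from
counts with half-up rounding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .anchor import AlignParams, build_coordinate_map
from .core import TemplateRecord, ValidationError
from .pairing import PairedSiteRegistry

__all__ = [
    "PAIR_PATTERNS",
    "CloneRecord",
    "CloneSummary",
    "pattern_of",
    "percent",
    "summarize_clones",
    "compare_libraries",
]

logger = logging.getLogger(__name__)

PAIR_PATTERNS = ("A-G", "A-U", "C-G", "C-U")

_PROTEO_CLASSES = {"alpha", "beta", "gamma", "delta", "epsilon", "zeta"}


def percent(count: int, total: int) -> int:
    """Integer percentage with half-up rounding (e.g. 52/61 -> 85)."""
    if total <= 0:
        raise ValidationError("percentage of an empty set is undefined")
    x = 100.0 * count / total
    return int(x + 0.5)


def pattern_of(base_19: str | None, base_916: str | None) -> str:
    """19-916 pattern label; 916 is displayed in RNA alphabet (U)."""
    if base_19 is None or base_916 is None:
        return "absent"
    b19 = base_19.upper().replace("U", "T")
    b916 = base_916.upper().replace("U", "T")
    label = f"{b19}-{'U' if b916 == 'T' else b916}"
    return label if label in PAIR_PATTERNS else "other"


@dataclass
class CloneRecord:
    """One sequenced (or pre-tabulated) clone from a library.

    Either ``sequence`` is present (pair states are then derived from it
    via coordinate mapping) or explicit ``base_19``/``base_916`` states
    plus a taxon label are given.
    """

    id: str
    library: str
    taxon_class: str = ""
    sequence: str | None = None
    base_19: str | None = None
    base_916: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is None and (self.base_19 is None or self.base_916 is None):
            raise ValidationError(
                f"clone {self.id!r}: needs a sequence or explicit "
                "base_19/base_916 states")


@dataclass
class CloneSummary:
    """Counts of one library by origin and by 19-916 pattern."""

    library: str
    origin_counts: dict[str, int]
    pair_counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.origin_counts.values())

    def origin_percentages(self) -> dict[str, int]:
        if self.total == 0:
            raise ValidationError(f"library {self.library!r} is empty; "
                                  "percentages undefined")
        return {k: percent(v, self.total) for k, v in self.origin_counts.items()}

    def pair_percentages(self) -> dict[str, int]:
        if self.total == 0:
            raise ValidationError(f"library {self.library!r} is empty; "
                                  "percentages undefined")
        return {k: percent(v, self.total) for k, v in self.pair_counts.items()}

    def proteobacterial_fraction(self) -> float:
        """Fraction of clones with a proteobacterial origin label."""
        n = sum(v for k, v in self.origin_counts.items() if _is_proteobacterial(k))
        return n / self.total if self.total else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"section": "origin", "key": k, "count": v}
                for k, v in sorted(self.origin_counts.items())]
        rows += [{"section": "pair", "key": k, "count": self.pair_counts.get(k, 0)}
                 for k in (*PAIR_PATTERNS, "other", "absent")
                 if k in self.pair_counts or k in PAIR_PATTERNS]
        df = pd.DataFrame(rows)
        df["library"] = self.library
        if self.total:
            df["percent"] = [percent(c, self.total) for c in df["count"]]
        return df[["library", "section", "key", "count"] +
                  (["percent"] if self.total else [])]


def _is_proteobacterial(label: str) -> bool:
    s = label.strip().lower()
    return "proteobacteria" in s or s in _PROTEO_CLASSES


def _derive_states(rec: CloneRecord, reference: str,
                   registry: PairedSiteRegistry,
                   params: AlignParams) -> tuple[str | None, str | None]:
    a, b = registry.focus_pair
    cmap = build_coordinate_map(
        TemplateRecord(id=rec.id, sequence=rec.sequence), reference, params)
    if not cmap.anchorable:
        return None, None
    return cmap.base_at(rec.sequence, a), cmap.base_at(rec.sequence, b)


def summarize_clones(records: Sequence[CloneRecord],
                     reference: str | None = None,
                     registry: PairedSiteRegistry = PairedSiteRegistry(),
                     params: AlignParams = AlignParams(),
                     ) -> dict[str, CloneSummary]:
    """Summarize clone records into per-library contingency tables.

    For records carrying a sequence, the 19/916 states are extracted via
    a coordinate map against ``reference`` (the packaged reference by
    default); sequence-derived states win over explicit ones and any
    discrepancy is logged.
    """
    if any(r.sequence is not None for r in records) and reference is None:
        from .io import load_packaged_reference
        reference = load_packaged_reference()

    by_library: dict[str, CloneSummary] = {}
    for rec in sorted(records, key=lambda r: (r.library, r.id)):
        if rec.sequence is not None:
            b19, b916 = _derive_states(rec, reference, registry, params)
            if rec.base_19 is not None and (rec.base_19, rec.base_916) != (b19, b916):
                logger.warning(
                    "clone %s: explicit states (%s, %s) differ from "
                    "sequence-derived (%s, %s); using sequence",
                    rec.id, rec.base_19, rec.base_916, b19, b916)
        else:
            b19, b916 = rec.base_19, rec.base_916
        summary = by_library.setdefault(
            rec.library, CloneSummary(rec.library, {}, {}))
        origin = rec.taxon_class or "unclassified"
        summary.origin_counts[origin] = summary.origin_counts.get(origin, 0) + 1
        pat = pattern_of(b19, b916)
        summary.pair_counts[pat] = summary.pair_counts.get(pat, 0) + 1
    return by_library


def compare_libraries(summaries: Iterable[CloneSummary] | Mapping[str, CloneSummary],
                      ) -> pd.DataFrame:
    """Side-by-side composition of two or more libraries.

    One row per library: total, origin percentages, pair-pattern
    percentages, and the proteobacterial fraction as an integer percent.
    """
    if isinstance(summaries, Mapping):
        summaries = list(summaries.values())
    else:
        summaries = list(summaries)
    if len(summaries) < 2:
        raise ValidationError("compare_libraries needs at least two summaries")
    rows = []
    for s in summaries:
        if s.total == 0:
            raise ValidationError(f"library {s.library!r} is empty")
        row: dict[str, object] = {"library": s.library, "total": s.total}
        for k, v in sorted(s.origin_counts.items()):
            row[f"origin%:{k}"] = percent(v, s.total)
        for k in PAIR_PATTERNS:
            row[f"pair%:{k}"] = percent(s.pair_counts.get(k, 0), s.total)
        row["proteobacteria%"] = percent(
            sum(v for k, v in s.origin_counts.items() if _is_proteobacterial(k)),
            s.total)
        rows.append(row)
    return pd.DataFrame(rows).set_index("library").fillna(0)
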