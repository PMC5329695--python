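"""Per-position nucleotide composition and primer coverage rates.

Composition profiles tally, for every E. coli position in a region, the
bases found across a template collection (gap where a template does not
span or has a deletion at the position). Coverage of a primer is the
fraction of anchorable templates it matches within a mismatch tolerance
(default 0: every footprint position IUPAC-compatible). Variable-site
reports flag footprint positions whose minor-allele frequency exceeds a
threshold, annotated with base-pairing status from a paired-site
registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from . import iupac
from .anchor import CoordinateMap, anchor_primer
from .core import Primer, TemplateRecord, ValidationError

if TYPE_CHECKING:
    from .pairing import PairedSiteRegistry

__all__ = [
    "CompositionProfile",
    "CoverageReport",
    "VariableSiteReport",
    "composition_profile",
    "coverage_rate",
    "variable_sites_in_footprint",
]

BASES = ("A", "C", "G", "T")
COLUMNS = BASES + ("gap",)


@dataclass
class CompositionProfile:
    """Base counts per E. coli position over a template collection.

    ``counts`` is indexed by E. coli position with columns A, C, G, T,
    gap; every row sums to ``n_templates`` (anchorable templates only).
    Ambiguous template bases are tallied under gap (unresolved).
    """

    region: tuple[int, int]
    counts: pd.DataFrame
    n_templates: int

    def frequencies(self, include_gap: bool = True) -> pd.DataFrame:
        """Per-position allele frequencies; rows sum to 1.

        With ``include_gap=False`` frequencies are over called bases
        only (positions with zero called bases yield NaN).
        """
        cols = list(COLUMNS) if include_gap else list(BASES)
        sub = self.counts[cols]
        return sub.div(sub.sum(axis=1), axis=0)

    def depth(self) -> pd.Series:
        return self.counts[list(COLUMNS)].sum(axis=1)


@dataclass
class CoverageReport:
    """Coverage of one primer, overall and optionally per taxon group."""

    primer_name: str
    max_mismatch: int
    table: pd.DataFrame  # index: group; columns n_total, n_anchorable, n_covered, coverage_rate

    @property
    def overall_rate(self) -> float:
        return float(self.table.loc["overall", "coverage_rate"])


@dataclass
class VariableSiteReport:
    """Polymorphic positions inside a primer footprint."""

    primer_name: str
    footprint: tuple[int, int]
    minor_freq_threshold: float
    sites: pd.DataFrame  # ecoli_pos, major_allele, freq columns, minor_freq, in_paired_site, partner_pos

    @property
    def positions(self) -> list[int]:
        return [int(p) for p in self.sites["ecoli_pos"]]


def composition_profile(templates: Sequence[TemplateRecord],
                        maps: dict[str, CoordinateMap],
                        region: tuple[int, int]) -> CompositionProfile:
    """Tally bases at every E. coli position of ``region`` across all
    anchorable templates; a template not spanning a position (or gapped
    there) contributes gap."""
    lo, hi = region
    if not (1 <= lo <= hi <= 1542):
        raise ValidationError(f"region {region} outside [1, 1542]")
    anchorable = [t for t in templates if maps[t.id].anchorable]
    if not anchorable:
        raise ValidationError("no anchorable templates in collection")

    positions = np.arange(lo, hi + 1)
    counts = pd.DataFrame(0, index=pd.Index(positions, name="ecoli_pos"),
                          columns=list(COLUMNS))
    for t in anchorable:
        cmap = maps[t.id]
        for pos in positions:
            base = cmap.base_at(t, int(pos))
            col = base if base in BASES else "gap"
            counts.at[pos, col] += 1
    return CompositionProfile(region=(lo, hi), counts=counts,
                              n_templates=len(anchorable))


def coverage_rate(primer: Primer,
                  templates: Sequence[TemplateRecord],
                  maps: dict[str, CoordinateMap],
                  max_mismatch: int = 0,
                  window: int = 100,
                  group_by: str | None = None,
                  strict_denominator: bool = False) -> CoverageReport:
    """Fraction of templates the primer matches within ``max_mismatch``.

    A template is covered iff its map is anchorable, the primer places
    (anchored) and the placement has at most ``max_mismatch``
    IUPAC-incompatible positions. Unanchorable templates are excluded
    from the denominator (reported via n_total - n_anchorable) unless
    ``strict_denominator``, which counts them as uncovered. ``group_by``
    is None (overall only), "phylum" or "class".
    """
    if max_mismatch < 0:
        raise ValidationError("max_mismatch must be >= 0")
    rows = []
    for t in templates:
        cmap = maps[t.id]
        covered = False
        if cmap.anchorable:
            m = anchor_primer(primer, t, cmap, window=window)
            covered = m.anchored and m.n_mismatches <= max_mismatch
        rows.append({"phylum": t.taxon_phylum, "class": t.taxon_class,
                     "anchorable": cmap.anchorable, "covered": covered})
    df = pd.DataFrame(rows)

    def summarize(sub: pd.DataFrame) -> dict:
        n_total = len(sub)
        n_anch = int(sub["anchorable"].sum())
        n_cov = int(sub["covered"].sum())
        denom = n_total if strict_denominator else n_anch
        rate = n_cov / denom if denom > 0 else float("nan")
        return {"n_total": n_total, "n_anchorable": n_anch,
                "n_covered": n_cov, "coverage_rate": rate}

    out = {"overall": summarize(df)}
    if group_by is not None:
        if group_by not in ("phylum", "class"):
            raise ValidationError(f"group_by must be 'phylum' or 'class', got {group_by!r}")
        for key, sub in df.groupby(group_by, sort=True):
            if key == "" :
                key = "(unlabelled)"
            out[str(key)] = summarize(sub)
    table = pd.DataFrame(out).T
    table.index.name = "group"
    for col in ("n_total", "n_anchorable", "n_covered"):
        table[col] = table[col].astype(int)
    return CoverageReport(primer.name, max_mismatch, table)


def variable_sites_in_footprint(primer: Primer,
                                profile: CompositionProfile,
                                registry: "PairedSiteRegistry | None" = None,
                                minor_freq_threshold: float = 0.05) -> VariableSiteReport:
    """Footprint positions whose minor-allele frequency (over called
    bases) reaches the threshold, annotated with pairing status."""
    if not (0 < minor_freq_threshold <= 0.5):
        raise ValidationError("minor_freq_threshold must be in (0, 0.5]")
    if primer.intended_footprint is None:
        raise ValidationError(f"primer {primer.name!r} has no intended footprint")
    lo, hi = primer.intended_footprint
    plo, phi = profile.region
    if lo < plo or hi > phi:
        raise ValidationError(
            f"footprint {lo}-{hi} outside profile region {plo}-{phi}")

    freqs = profile.frequencies(include_gap=False)
    rows = []
    for pos in range(lo, hi + 1):
        f = freqs.loc[pos]
        if f.isna().any():
            continue
        major = f.idxmax()
        minor_freq = float(1.0 - f.max())
        if minor_freq >= minor_freq_threshold:
            partner = registry.partner_of(pos) if registry is not None else None
            rows.append({
                "ecoli_pos": pos,
                "major_allele": major,
                **{f"freq_{b}": float(f[b]) for b in BASES},
                "minor_freq": minor_freq,
                "in_paired_site": partner is not None,
                "partner_pos": partner,
            })
    sites = pd.DataFrame(rows, columns=[
        "ecoli_pos", "major_allele", "freq_A", "freq_C", "freq_G", "freq_T",
        "minor_freq", "in_paired_site", "partner_pos"])
    return VariableSiteReport(primer.name, (lo, hi), minor_freq_threshold, sites)
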