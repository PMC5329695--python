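"""Synthetic 16S-like template collections and clone sets.

The generator emulates the statistical structure the analysis assumes
in real 16S gene collections: a hypervariable 5' region (positions
1-7), a conserved 8-27 block under the forward-primer footprints,
class-linked covariation of the 19-916 pseudoknot pair (gamma-like
19A-916U, beta-like 19C-916G), the variable lone site 1527 (C/U),
~50-nt flanks, background substitutions outside conserved blocks,
optional deletions in designated variable-helix windows, and occasional
severe truncation. Every planted state is returned in a ground-truth
table so each pipeline stage can be checked against it.

A single seeded RNG stream drives the whole corpus: identical config
and seed reproduce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import iupac
from .clones import PAIR_PATTERNS, CloneRecord
from .core import Primer, TemplateRecord, ValidationError

__all__ = ["SyntheticConfig", "generate_templates", "generate_clone_set"]

_BASES = "ACGT"

# gene regions held fixed unless explicitly varied (primer footprints and
# the pseudoknot partner strand); 1-based closed intervals
CONSERVED_BLOCKS = ((8, 27), (914, 920), (1525, 1542))
FIVE_PRIME_VARIABLE = (1, 7)

_TAXONOMY = {
    "gamma_like": ("Proteobacteria", "Gammaproteobacteria"),
    "beta_like": ("Proteobacteria", "Betaproteobacteria"),
    "other": ("Firmicutes", "Bacilli"),
}

_NATIVE_PARTNER = {"A": "T", "C": "G"}  # 19 -> its native 916 partner


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions for one synthetic corpus.

    Defaults describe a gamma-dominated proteobacterial mix with fully
    class-consistent 19-916 pairing, an even 1527 C/U split, a strongly
    variable 5' heptamer and a 2% background substitution rate — the
    regime the audited primers are designed for.
    """

    seed: int = 0
    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"gamma_like": 50, "beta_like": 30, "other": 20})
    freq_19A: dict[str, float] = field(
        default_factory=lambda: {"gamma_like": 1.0, "beta_like": 0.0, "other": 0.5})
    pair_consistency: float = 1.0
    freq_1527: dict[str, float] = field(
        default_factory=lambda: {"C": 0.5, "U": 0.5})
    five_prime_variability: float = 0.5
    core_mutation_rate: float = 0.02
    indel_model: dict | None = None  # {"windows": [(lo, hi), ...], "rate": p, "max_len": n}
    flank_length: int = 50
    truncation_rate: float = 0.0

    def __post_init__(self) -> None:
        for name, p in (("pair_consistency", self.pair_consistency),
                        ("five_prime_variability", self.five_prime_variability),
                        ("core_mutation_rate", self.core_mutation_rate),
                        ("truncation_rate", self.truncation_rate),
                        *((f"freq_19A[{k}]", v) for k, v in self.freq_19A.items()),
                        *((f"freq_1527[{k}]", v) for k, v in self.freq_1527.items())):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} = {p} outside [0, 1]")
        if any(n < 0 for n in self.n_per_class.values()):
            raise ValidationError("n_per_class counts must be >= 0")
        if abs(sum(self.freq_1527.values()) - 1.0) > 1e-9:
            raise ValidationError("freq_1527 probabilities must sum to 1")

    @classmethod
    def mutation_free(cls, **overrides) -> "SyntheticConfig":
        """All variability off: every template equals the reference."""
        base = cls(five_prime_variability=0.0, core_mutation_rate=0.0,
                   freq_1527={"C": 1.0, "U": 0.0}, flank_length=0,
                   truncation_rate=0.0)
        return replace(base, **overrides)


def _mutate(rng: np.random.Generator, base: str) -> str:
    return rng.choice([b for b in _BASES if b != base])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _footprint_mismatches(primer: Primer, gene: str) -> int:
    """Mismatches of a primer at its design site on the terminal region
    of an (un-truncated, flank-free) gene."""
    probe = primer.plus_strand_sequence
    lo, hi = primer.intended_footprint
    if primer.orientation == "forward":
        site = gene[lo - 1: lo - 1 + len(probe)]
    else:
        site = gene[len(gene) - (1542 - lo + 1): len(gene) - (1542 - hi)]
    if len(site) != len(probe):
        return len(probe)
    return sum(not iupac.iupac_match(p, t) for p, t in zip(probe, site))


def generate_templates(config: SyntheticConfig,
                       reference: str | None = None,
                       ) -> tuple[list[TemplateRecord], pd.DataFrame]:
    """Generate a template collection plus its ground-truth table.

    Ground truth records, per template: class label, planted bases at
    19/916/1527, truncation flag, and the mismatch count of each
    packaged amplification primer at its design footprint.
    """
    if sum(config.n_per_class.values()) == 0:
        raise ValidationError("total template count is zero")
    if reference is None:
        from .io import load_packaged_reference
        reference = load_packaged_reference()
    if len(reference) != 1542:
        raise ValidationError(f"reference must be 1542 nt, got {len(reference)}")
    from .io import load_packaged_primers
    primers = load_packaged_primers()

    rng = np.random.default_rng(config.seed)
    conserved = np.zeros(len(reference), dtype=bool)
    for lo, hi in CONSERVED_BLOCKS:
        conserved[lo - 1: hi] = True

    labels_1527 = list(config.freq_1527)
    probs_1527 = [config.freq_1527[k] for k in labels_1527]

    records: list[TemplateRecord] = []
    truth_rows: list[dict] = []
    for class_label in sorted(config.n_per_class):
        phylum, klass = _TAXONOMY[class_label]
        for i in range(config.n_per_class[class_label]):
            tid = f"{class_label}_{i + 1:04d}"
            gene = list(reference)

            b19 = "A" if rng.random() < config.freq_19A[class_label] else "C"
            native = _NATIVE_PARTNER[b19]
            b916 = (native if rng.random() < config.pair_consistency
                    else _NATIVE_PARTNER["C" if b19 == "A" else "A"])
            b1527 = labels_1527[rng.choice(len(labels_1527), p=probs_1527)]
            gene[18] = b19
            gene[915] = b916
            gene[1526] = b1527.replace("U", "T")

            lo, hi = FIVE_PRIME_VARIABLE
            for p in range(lo - 1, hi):
                if rng.random() < config.five_prime_variability:
                    gene[p] = _mutate(rng, gene[p])
            if config.core_mutation_rate > 0:
                lo7 = FIVE_PRIME_VARIABLE[1]
                hits = np.nonzero(rng.random(len(gene)) < config.core_mutation_rate)[0]
                for p in hits:
                    if not conserved[p] and p >= lo7 and p not in (18, 915, 1526):
                        gene[p] = _mutate(rng, gene[p])
            gene = "".join(gene)

            if config.indel_model:
                windows = config.indel_model.get("windows", ())
                rate = config.indel_model.get("rate", 0.0)
                max_len = int(config.indel_model.get("max_len", 3))
                for wlo, whi in windows:
                    if rng.random() < rate:
                        dlen = int(rng.integers(1, max_len + 1))
                        dstart = int(rng.integers(wlo - 1, whi - dlen))
                        gene = gene[:dstart] + gene[dstart + dlen:]

            mm = {p.name: _footprint_mismatches(p, gene)
                  for p in primers.values()}

            truncated = rng.random() < config.truncation_rate
            if truncated:
                # keep only a short internal fragment, below anchoring floor
                frag = int(rng.integers(80, 151))
                start = int(rng.integers(0, len(gene) - frag + 1))
                seq = gene[start: start + frag]
                has_flanks = False
            else:
                seq = (_random_seq(rng, config.flank_length) + gene
                       + _random_seq(rng, config.flank_length)
                       if config.flank_length > 0 else gene)
                has_flanks = config.flank_length > 0

            records.append(TemplateRecord(
                id=tid, sequence=seq, taxon_phylum=phylum,
                taxon_class=klass, has_flanks=has_flanks))
            truth_rows.append({
                "id": tid, "class_label": class_label, "phylum": phylum,
                "class": klass, "base_19": b19, "base_916": b916,
                "base_1527": b1527, "truncated": truncated,
                **{f"n_mm_{name}": n for name, n in mm.items()},
            })
    return records, pd.DataFrame(truth_rows).set_index("id")


_PATTERN_BASES = {"A-G": ("A", "G"), "A-U": ("A", "T"),
                  "C-G": ("C", "G"), "C-U": ("C", "T")}


def generate_clone_set(library: str,
                       pair_counts: dict[str, int],
                       origin_counts: dict[str, int] | None = None,
                       seed: int = 0,
                       reference: str | None = None,
                       background_rate: float = 0.005,
                       ) -> list[CloneRecord]:
    """Clone records with sequences planted to given 19-916 patterns.

    ``pair_counts`` maps patterns ("A-G", "A-U", "C-G", "C-U") to clone
    counts; ``origin_counts`` (taxon-class label -> count) must total
    the same and is assigned across the pattern sequence in a fixed
    deterministic order. Background substitutions avoid primer
    footprints and pseudoknot sites so planted states survive the full
    sequence-level round trip.
    """
    bad = set(pair_counts) - set(PAIR_PATTERNS)
    if bad:
        raise ValidationError(f"unknown pair pattern(s): {sorted(bad)}")
    total = sum(pair_counts.values())
    if total == 0:
        raise ValidationError("clone set is empty")
    if origin_counts is not None and sum(origin_counts.values()) != total:
        raise ValidationError(
            f"origin counts total {sum(origin_counts.values())} != "
            f"pair counts total {total}")
    if reference is None:
        from .io import load_packaged_reference
        reference = load_packaged_reference()

    rng = np.random.default_rng(seed)
    patterns = [p for p in PAIR_PATTERNS for _ in range(pair_counts.get(p, 0))]
    origins = (["unclassified"] * total if origin_counts is None
               else [k for k in sorted(origin_counts)
                     for _ in range(origin_counts[k])])

    protected = np.zeros(len(reference), dtype=bool)
    for lo, hi in ((1, 27), (914, 920), (1525, 1542)):
        protected[lo - 1: hi] = True

    records = []
    for i, (pat, origin) in enumerate(zip(patterns, origins)):
        b19, b916 = _PATTERN_BASES[pat]
        seq = list(reference)
        seq[18], seq[915] = b19, b916
        hits = np.nonzero(rng.random(len(seq)) < background_rate)[0]
        for p in hits:
            if not protected[p]:
                seq[p] = _mutate(rng, seq[p])
        records.append(CloneRecord(
            id=f"{library}_clone_{i + 1:03d}", library=library,
            taxon_class=origin, sequence="".join(seq)))
    return records
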