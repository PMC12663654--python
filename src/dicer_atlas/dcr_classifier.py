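"""Dicer gate, six-category architecture classification and summaries.

A protein is called a putative Dicer (Dcr) when it carries two tandem
RNase III domains plus at least one RNA-binding domain (any helicase
subdomain, DUF283, PAZ or dsRBD). Gate-passing proteins are then placed
into six categories from the pattern of *missing* domain units, where the
units are HEL (any of DEAD/ResIII/HeliC), DUF283, PAZ and dsRBD:

================  =============================
missing set M     category
================  =============================
{}                canonical
{dsRBD}           non-canonical A
{PAZ}             non-canonical B
{HEL, dsRBD}      non-canonical C
{PAZ, dsRBD}      non-canonical D
anything else     non-canonical E (catch-all)
================  =============================

Category E is the catch-all for every other missing pattern, including
all patterns with three or more missing units and any pattern involving
DUF283. With it, the six categories are mutually exclusive and exhaustive
over gate-passing architectures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .domain_hits import Architecture, HELICASE_LABELS

logger = logging.getLogger(__name__)

CATEGORIES = ("canonical", "nonA", "nonB", "nonC", "nonD", "nonE")

#: Exact missing-unit patterns for the named categories (frozen rule table).
_PATTERN_TO_CATEGORY = {
    frozenset(): "canonical",
    frozenset({"dsRBD"}): "nonA",
    frozenset({"PAZ"}): "nonB",
    frozenset({"HEL", "dsRBD"}): "nonC",
    frozenset({"PAZ", "dsRBD"}): "nonD",
}

_UNITS = ("HEL", "DUF283", "PAZ", "dsRBD")

#: Categories whose members lack a sequence-detectable (canonical) PAZ.
CPAZ_LACKING = ("nonB", "nonD", "nonE")


def dcr_gate(arch: Architecture) -> bool:
    """True iff the architecture passes the Dicer criteria.

    Requires >= 2 retained (non-overlapping) RNase III hits and at least
    one RNA-binding domain among DEAD, ResIII, HeliC, DUF283, PAZ, dsRBD.
    """
    if arch.rnase3_count < 2:
        return False
    flags = arch.unit_flags
    return flags["HEL_any"] or flags["DUF283"] or flags["PAZ"] or flags["dsRBD"]


def missing_units(arch: Architecture) -> frozenset[str]:
    """The set of absent domain units among HEL/DUF283/PAZ/dsRBD."""
    flags = arch.unit_flags
    present = {
        "HEL": flags["HEL_any"],
        "DUF283": flags["DUF283"],
        "PAZ": flags["PAZ"],
        "dsRBD": flags["dsRBD"],
    }
    return frozenset(u for u in _UNITS if not present[u])


def classify(arch: Architecture) -> str:
    """Assign the six-category label to a gate-passing architecture."""
    if not dcr_gate(arch):
        raise ValueError(f"{arch.protein_id}: classify() called on a non-Dcr architecture")
    return _PATTERN_TO_CATEGORY.get(missing_units(arch), "nonE")


def helicase_complete(arch: Architecture) -> bool:
    """All three helicase subdomains retained (metadata, not a category rule)."""
    labels = {h.domain_label for h in arch.hits}
    return HELICASE_LABELS <= labels


def terminal_lengths(arch: Architecture) -> tuple[int | None, int | None]:
    """N/C-terminal lengths to the nearest highly conserved domains.

    The N-terminal length is the residue count before the DUF283 hit
    (undefined without DUF283); the C-terminal length is the residue
    count after the second RNase III hit in start order — RNase IIIb —
    (undefined with fewer than two RNase III hits).
    """
    n_term = None
    duf = arch.hits_for("DUF283")
    if duf:
        n_term = duf[0].start - 1
    c_term = None
    rnase = arch.hits_for("RNaseIII")
    if len(rnase) >= 2:
        c_term = arch.protein_length - rnase[1].end
    return n_term, c_term


@dataclass
class DcrRecord:
    """A classified protein with its metadata."""

    arch: Architecture
    species: str | None = None
    phylum: str | None = None
    gene_id: str | None = None
    locus: str | None = None
    uniprot_id: str | None = None
    sequence: str | None = None
    is_dcr: bool = False
    category: str = "none"
    n_term_len: int | None = None
    c_term_len: int | None = None
    helicase_complete: bool = False

    @property
    def protein_id(self) -> str:
        return self.arch.protein_id


def build_record(arch: Architecture, **metadata) -> DcrRecord:
    """Gate, classify and annotate one architecture."""
    rec = DcrRecord(arch=arch, **metadata)
    rec.is_dcr = dcr_gate(arch)
    if rec.is_dcr:
        rec.category = classify(arch)
        rec.n_term_len, rec.c_term_len = terminal_lengths(arch)
        rec.helicase_complete = helicase_complete(arch)
    return rec


def deduplicate(records: Sequence[DcrRecord]) -> list[DcrRecord]:
    """Collapse annotation duplicates, keeping isoforms.

    Records of the same species with byte-identical sequence and the same
    UniProt accession are annotation duplicates: only the one with the
    lexicographically smallest protein accession is kept. Records sharing
    gene_id and locus but differing in sequence are isoforms and all kept.
    Records with missing species/sequence/UniProt metadata pass through
    untouched (logged).
    """
    passthrough: set[int] = set()
    best: dict[tuple, DcrRecord] = {}
    for rec in records:
        if rec.species is None or rec.sequence is None or rec.uniprot_id is None:
            logger.info("record %s lacks dedup metadata; passed through",
                        rec.protein_id)
            passthrough.add(id(rec))
            continue
        key = (rec.species, rec.sequence, rec.uniprot_id)
        if key not in best or rec.protein_id < best[key].protein_id:
            best[key] = rec
    winners = {id(r) for r in best.values()}
    return [r for r in records if id(r) in winners or id(r) in passthrough]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 62.65 -> 62.7, not banker's 62.6)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def share_percentages(counts: Mapping[str, int], ndigits: int = 1) -> dict[str, float]:
    """Per-key percentage of the total, rounded half-up to ``ndigits``."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty counts")
    return {k: round_half_up(100.0 * v / total, ndigits) for k, v in counts.items()}


@dataclass
class CategorySummary:
    """Counts, percentages and cross-tabulations over classified records."""

    counts: dict[str, int]
    percentages: dict[str, float]
    cpaz_lacking_percent: float
    by_phylum: pd.DataFrame = field(default_factory=pd.DataFrame)
    copy_number_histogram: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def summarize_counts(counts: Mapping[str, int]) -> CategorySummary:
    """Summary statistics from per-category Dcr counts alone."""
    counts = {c: int(counts.get(c, 0)) for c in CATEGORIES}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no Dcr records to summarize")
    pct = share_percentages(counts)
    cpaz_lacking = round_half_up(
        100.0 * sum(counts[c] for c in CPAZ_LACKING) / total
    )
    return CategorySummary(counts=counts, percentages=pct,
                           cpaz_lacking_percent=cpaz_lacking)


def summarize(records: Iterable[DcrRecord]) -> CategorySummary:
    """Counts, one-decimal percentages, per-phylum cross-tab and the
    per-proteome (species) Dcr copy-number histogram."""
    dcrs = [r for r in records if r.is_dcr]
    counts = {c: 0 for c in CATEGORIES}
    for r in dcrs:
        counts[r.category] += 1
    summary = summarize_counts(counts)

    frame = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in dcrs],
            "category": [r.category for r in dcrs],
            "phylum": [r.phylum or "unknown" for r in dcrs],
            "species": [r.species or r.protein_id for r in dcrs],
        }
    )
    if not frame.empty:
        summary.by_phylum = (
            frame.pivot_table(index="phylum", columns="category",
                              values="protein_id", aggfunc="count", fill_value=0)
            .reindex(columns=CATEGORIES, fill_value=0)
        )
        copies = frame.groupby("species").size()
        summary.copy_number_histogram = (
            copies.value_counts().sort_index().rename_axis("dcr_copies")
            .to_frame("n_proteomes")
        )
    return summary


def records_to_frame(records: Iterable[DcrRecord]) -> pd.DataFrame:
    """Flat table of classified records for TSV export."""
    rows = []
    for r in records:
        flags = r.arch.unit_flags
        rows.append(
            {
                "protein_id": r.protein_id,
                "protein_length": r.arch.protein_length,
                "species": r.species,
                "phylum": r.phylum,
                "is_dcr": r.is_dcr,
                "category": r.category,
                "rnase3_count": r.arch.rnase3_count,
                "HEL_any": flags["HEL_any"],
                "DUF283": flags["DUF283"],
                "PAZ": flags["PAZ"],
                "dsRBD": flags["dsRBD"],
                "helicase_complete": r.helicase_complete,
                "n_term_len": r.n_term_len,
                "c_term_len": r.c_term_len,
            }
        )
    return pd.DataFrame(rows)
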