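"""Parsing and filtering of profile-HMM domain hit tables.

Dicer identification starts from per-domain hits of seven conserved
profile HMMs (helicase subdomains DEAD, ResIII and HeliC; the dimerization
domain DUF283; PAZ; RNase III; and the dsRNA-binding domain dsRBD) against
a proteome. This module reads HMMER ``--domtblout`` tables (or a minimal
six-column TSV), applies the E-value cut-off, and assembles per-protein
domain architectures with overlaps resolved greedily by E-value.

Coordinates are 1-based inclusive amino-acid positions taken from the
envelope columns, following the HMMER convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

logger = logging.getLogger(__name__)

#: Canonical 7-label domain vocabulary.
DOMAIN_LABELS = ("DEAD", "ResIII", "HeliC", "DUF283", "PAZ", "RNaseIII", "dsRBD")

#: Pfam / InterPro accessions (and bare query names) mapped onto the vocabulary.
ACCESSION_TO_LABEL = {
    "PF00270": "DEAD", "IPR011545": "DEAD", "DEAD": "DEAD",
    "PF04851": "ResIII", "IPR006935": "ResIII", "ResIII": "ResIII",
    "PF00271": "HeliC", "IPR001650": "HeliC", "HeliC": "HeliC",
    "Helicase_C": "HeliC",
    "PF03368": "DUF283", "IPR005034": "DUF283", "DUF283": "DUF283",
    "Dicer_dimer": "DUF283",
    "PF02170": "PAZ", "IPR003100": "PAZ", "PAZ": "PAZ",
    "PF00636": "RNaseIII", "IPR000999": "RNaseIII", "RNaseIII": "RNaseIII",
    "Ribonuclease_3": "RNaseIII",
    "PF00035": "dsRBD", "IPR014720": "dsRBD", "dsRBD": "dsRBD", "dsrm": "dsRBD",
}

#: Default per-domain (independent) E-value threshold, inclusive.
DEFAULT_EVALUE_MAX = 1e-3

#: Helicase-unit member labels.
HELICASE_LABELS = frozenset({"DEAD", "ResIII", "HeliC"})


class MalformedRowError(ValueError):
    """A hit-table data row with the wrong column count."""


@dataclass(frozen=True, order=True)
class DomainHit:
    """One profile-HMM match on one protein.

    ``start``/``end`` are 1-based inclusive envelope coordinates;
    ``evalue`` is the per-domain independent E-value and ``score`` the
    domain bit score.
    """

    protein_id: str
    domain_label: str
    start: int
    end: int
    evalue: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.domain_label not in DOMAIN_LABELS:
            raise ValueError(f"unknown domain label {self.domain_label!r}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")

    def overlaps(self, other: "DomainHit") -> bool:
        """True if the two hits share at least one residue."""
        return self.start <= other.end and other.start <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def map_label(raw: str) -> str | None:
    """Map a query name/accession to the 7-label vocabulary, or None.

    Versioned Pfam accessions (``PF00636.27``) are accepted.
    """
    token = raw.split(".")[0]
    return ACCESSION_TO_LABEL.get(token) or ACCESSION_TO_LABEL.get(raw)


# -- column indices of HMMER 3.x --domtblout (whitespace-delimited) -------
# 0 target name, 1 target acc, 2 tlen, 3 query name, 4 query acc, 5 qlen,
# 6 full E-value, 7 full score, 8 full bias, 9 dom #, 10 dom of,
# 11 c-Evalue, 12 i-Evalue, 13 dom score, 14 dom bias,
# 15 hmm from, 16 hmm to, 17 ali from, 18 ali to, 19 env from, 20 env to,
# 21 acc, 22.. description
_DOMTBLOUT_MIN_COLS = 22


def parse_domtblout(stream: TextIO | Iterable[str]) -> list[DomainHit]:
    """Parse a HMMER ``--domtblout`` table into :class:`DomainHit` records.

    Envelope coordinates and the per-domain independent E-value are used.
    Rows whose query cannot be mapped onto the domain vocabulary are
    dropped with a logged warning; comment lines (``#``) are skipped.

    Raises :class:`MalformedRowError` (with the line number) on rows with
    too few columns.
    """
    hits: list[DomainHit] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split()
        if len(cols) < _DOMTBLOUT_MIN_COLS:
            raise MalformedRowError(
                f"line {lineno}: expected >= {_DOMTBLOUT_MIN_COLS} columns, "
                f"got {len(cols)}"
            )
        label = map_label(cols[3]) or map_label(cols[4])
        if label is None:
            logger.warning(
                "line %d: query %r/%r not in the domain vocabulary; row dropped",
                lineno, cols[3], cols[4],
            )
            continue
        hits.append(
            DomainHit(
                protein_id=cols[0],
                domain_label=label,
                start=int(cols[19]),
                end=int(cols[20]),
                evalue=float(cols[12]),
                score=float(cols[13]),
            )
        )
    return hits


def parse_hits_tsv(stream: TextIO | Iterable[str]) -> list[DomainHit]:
    """Parse the minimal 6-column hit TSV.

    Columns: protein_id, domain_label, start, end, evalue, score.
    A header line starting with ``protein_id`` and comments are skipped.
    """
    hits: list[DomainHit] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#") or line.startswith("protein_id"):
            continue
        cols = line.split("\t")
        if len(cols) != 6:
            raise MalformedRowError(
                f"line {lineno}: expected 6 tab-separated columns, got {len(cols)}"
            )
        label = map_label(cols[1])
        if label is None:
            logger.warning("line %d: unknown domain label %r; row dropped",
                           lineno, cols[1])
            continue
        hits.append(
            DomainHit(cols[0], label, int(cols[2]), int(cols[3]),
                      float(cols[4]), float(cols[5]))
        )
    return hits


def write_hits_tsv(hits: Sequence[DomainHit], stream: TextIO,
                   header: bool = True) -> None:
    """Write hits in the minimal 6-column TSV dialect (round-trips)."""
    if header:
        stream.write("protein_id\tdomain_label\tstart\tend\tevalue\tscore\n")
    for h in hits:
        stream.write(
            f"{h.protein_id}\t{h.domain_label}\t{h.start}\t{h.end}\t"
            f"{h.evalue!r}\t{h.score!r}\n"
        )


def filter_hits(hits: Sequence[DomainHit],
                evalue_max: float = DEFAULT_EVALUE_MAX) -> list[DomainHit]:
    """Retain hits with E-value <= ``evalue_max`` (inclusive), order kept."""
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    return [h for h in hits if h.evalue <= evalue_max]


def _priority(hit: DomainHit) -> tuple:
    # ascending E-value; ties: higher bit score, then smaller start
    return (hit.evalue, -hit.score, hit.start, hit.end, hit.domain_label)


def resolve_overlaps(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Greedy resolution of overlapping hits on one protein.

    Hits are taken in order of ascending E-value (ties: higher bit score,
    then smaller start); a hit is retained iff it shares no residue with
    any previously retained hit. The result is sorted by start.
    """
    retained: list[DomainHit] = []
    for hit in sorted(hits, key=_priority):
        if not any(hit.overlaps(r) for r in retained):
            retained.append(hit)
    retained.sort(key=lambda h: (h.start, h.end))
    return retained


@dataclass
class Architecture:
    """Per-protein ordered, overlap-resolved domain layout.

    ``unit_flags`` records presence of each domain unit; ``HEL_any`` is
    true when any helicase subdomain (DEAD, ResIII or HeliC) was retained.
    """

    protein_id: str
    protein_length: int
    hits: list[DomainHit] = field(default_factory=list)

    @property
    def unit_flags(self) -> dict[str, bool]:
        labels = {h.domain_label for h in self.hits}
        flags = {lab: lab in labels for lab in DOMAIN_LABELS if lab != "RNaseIII"}
        flags["HEL_any"] = bool(labels & HELICASE_LABELS)
        return flags

    @property
    def rnase3_count(self) -> int:
        return sum(1 for h in self.hits if h.domain_label == "RNaseIII")

    def hits_for(self, label: str) -> list[DomainHit]:
        """Retained hits for one label, in start order."""
        return [h for h in self.hits if h.domain_label == label]


def assemble_architecture(protein_id: str, protein_length: int,
                          hits: Sequence[DomainHit]) -> Architecture:
    """Build an :class:`Architecture` from the filtered hits of one protein.

    Overlapping hits are resolved greedily by ascending E-value. Raises
    ``ValueError`` if any hit extends past ``protein_length`` or belongs
    to a different protein.
    """
    for h in hits:
        if h.protein_id != protein_id:
            raise ValueError(
                f"hit on {h.protein_id!r} passed to architecture of {protein_id!r}"
            )
        if h.end > protein_length:
            raise ValueError(
                f"{protein_id}: hit {h.domain_label} ends at {h.end} "
                f"beyond protein length {protein_length}"
            )
    return Architecture(protein_id, protein_length, resolve_overlaps(hits))


def assemble_all(hits: Sequence[DomainHit],
                 protein_lengths: dict[str, int]) -> dict[str, Architecture]:
    """Group hits by protein and assemble one architecture per protein.

    Proteins present in ``protein_lengths`` but without hits get an empty
    architecture, so downstream gating sees the whole proteome.
    """
    by_protein: dict[str, list[DomainHit]] = {pid: [] for pid in protein_lengths}
    for h in hits:
        if h.protein_id not in by_protein:
            raise KeyError(f"no protein length for {h.protein_id!r}")
        by_protein[h.protein_id].append(h)
    return {
        pid: assemble_architecture(pid, protein_lengths[pid], group)
        for pid, group in by_protein.items()
    }
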