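"""Extraction of canonical and inferred fungal PAZ regions.

Most fungal Dicers lack a sequence-detectable PAZ domain even though
their length and predicted structures suggest the fold is still there.
For such proteins the divergent fungal PAZ (fPAZ) is taken to be the
inter-domain region between DUF283 and the first RNase III domain
(RNase IIIa, the upstream member of the tandem pair); where a PAZ hit
exists its envelope is the canonical PAZ (cPAZ) region directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO
from typing import Iterable, Mapping, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .domain_hits import Architecture

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PazRegion:
    """A cPAZ or fPAZ span on one protein (1-based inclusive)."""

    protein_id: str
    kind: str  # "cPAZ" | "fPAZ"
    start: int
    end: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("cPAZ", "fPAZ"):
            raise ValueError(f"kind must be cPAZ or fPAZ, got {self.kind!r}")
        if self.start > self.end:
            raise ValueError("empty or inverted region")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def extract_paz(arch: Architecture, sequence: str | None = None) -> PazRegion | None:
    """Extract the PAZ region of one gate-passing architecture.

    Returns the cPAZ (the PAZ hit envelope) when a PAZ hit was retained;
    otherwise, when DUF283 and at least one RNase III hit are present,
    the fPAZ spanning DUF283.end + 1 .. first RNase III start - 1.
    Returns ``None`` (logged) when neither applies or the inter-domain
    span is empty.
    """
    paz_hits = arch.hits_for("PAZ")
    if paz_hits:
        hit = paz_hits[0]
        seq = sequence[hit.start - 1:hit.end] if sequence else None
        return PazRegion(arch.protein_id, "cPAZ", hit.start, hit.end, seq)
    duf = arch.hits_for("DUF283")
    rnase = arch.hits_for("RNaseIII")
    if not duf or not rnase:
        logger.info("%s: no PAZ hit and no DUF283/RNaseIII bracket; skipped",
                    arch.protein_id)
        return None
    start = duf[0].end + 1
    end = rnase[0].start - 1
    if start > end:
        logger.info("%s: empty DUF283-RNaseIII inter-domain span; skipped",
                    arch.protein_id)
        return None
    seq = sequence[start - 1:end] if sequence else None
    return PazRegion(arch.protein_id, "fPAZ", start, end, seq)


def _header(region: PazRegion) -> str:
    return f"{region.protein_id}|{region.kind}|{region.start}-{region.end}"


def write_region_fasta(regions: Sequence[PazRegion],
                       sequences: Mapping[str, str],
                       stream: TextIO) -> None:
    """Write regions as FASTA with ``>protein_id|kind|start-end`` headers.

    ``sequences`` maps protein_id to the full-length protein sequence;
    it must cover every region span.
    """
    records = []
    for region in regions:
        full = sequences.get(region.protein_id)
        if full is None or len(full) < region.end:
            raise ValueError(
                f"sequence for {region.protein_id} missing or shorter than "
                f"region end {region.end}"
            )
        sub = full[region.start - 1:region.end]
        records.append(SeqRecord(Seq(sub), id=_header(region), description=""))
    SeqIO.write(records, stream, "fasta")


def parse_region_fasta(stream: TextIO) -> list[PazRegion]:
    """Inverse of :func:`write_region_fasta` (coordinates from headers)."""
    regions = []
    for rec in SeqIO.parse(stream, "fasta"):
        pid, kind, span = rec.id.split("|")
        start, end = (int(x) for x in span.split("-"))
        regions.append(PazRegion(pid, kind, start, end, str(rec.seq)))
    return regions


def regions_to_tsv(regions: Iterable[PazRegion], stream: TextIO) -> None:
    stream.write("protein_id\tkind\tstart\tend\tlength\n")
    for r in regions:
        stream.write(f"{r.protein_id}\t{r.kind}\t{r.start}\t{r.end}\t{r.length}\n")


def region_fasta_text(regions: Sequence[PazRegion],
                      sequences: Mapping[str, str]) -> str:
    buf = StringIO()
    write_region_fasta(regions, sequences, buf)
    return buf.getvalue()
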