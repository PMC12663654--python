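"""Structure-model metrics: mean pLDDT and the PAZ->RNase IIIa ruler.

AlphaFold writes its per-residue confidence (pLDDT, 0-100) into the PDB
B-factor column; the mean over CA atoms is the model-level confidence
used for filtering (models below 70 are discarded). The molecular-ruler
metric is the Euclidean CA-CA distance between the N-terminal residues
of the PAZ (or fPAZ) segment and of the RNase IIIa segment — the spacing
that sets the length of the small-RNA product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from io import StringIO

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Structure import Structure

DEFAULT_PLDDT_MIN = 70.0


@dataclass(frozen=True)
class ResidueInterval:
    """A named 1-based inclusive residue interval (e.g. a domain segment)."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.label}: start {self.start} > end {self.end}")


def parse_pdb(text_or_stream, model_id: str = "model") -> Structure:
    """Parse PDB text (string or stream); permissive about minor issues."""
    stream = StringIO(text_or_stream) if isinstance(text_or_stream, str) else text_or_stream
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return parser.get_structure(model_id, stream)


def _first_chain(structure: Structure):
    try:
        model = next(iter(structure))
        return next(iter(model))
    except StopIteration:
        raise ValueError("no CA atoms in the model (empty structure)") from None


def _ca_coords(structure: Structure) -> dict[int, np.ndarray]:
    """Residue number -> CA coordinate for the first chain of model 1."""
    chain = _first_chain(structure)
    coords = {}
    for residue in chain:
        if "CA" in residue:
            coords[residue.id[1]] = residue["CA"].coord.astype(float)
    return coords


def _ca_bfactors(structure: Structure) -> dict[int, float]:
    chain = _first_chain(structure)
    return {res.id[1]: float(res["CA"].bfactor) for res in chain if "CA" in res}


def mean_plddt(structure: Structure) -> float:
    """Arithmetic mean of CA B-factors (the per-residue pLDDT)."""
    values = list(_ca_bfactors(structure).values())
    if not values:
        raise ValueError("no CA atoms in the model")
    return float(np.mean(values))


def passes_plddt_filter(structure: Structure,
                        plddt_min: float = DEFAULT_PLDDT_MIN) -> bool:
    """Inclusive model-confidence filter (mean pLDDT >= threshold)."""
    return mean_plddt(structure) >= plddt_min


def ruler_distance(structure: Structure,
                   paz_interval: ResidueInterval,
                   rnase3a_interval: ResidueInterval) -> float:
    """Euclidean CA-CA distance (Å) between the segments' first residues.

    The N-terminus of each domain segment is taken to be the first
    residue of its interval. Raises ``KeyError`` naming the residue when
    its CA atom is absent.
    """
    coords = _ca_coords(structure)
    points = []
    for interval in (paz_interval, rnase3a_interval):
        if interval.start not in coords:
            raise KeyError(
                f"no CA atom for residue {interval.start} "
                f"({interval.label} N-terminus)"
            )
        points.append(coords[interval.start])
    return float(np.linalg.norm(points[0] - points[1]))
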