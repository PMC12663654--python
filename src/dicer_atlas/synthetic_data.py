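"""Synthetic inputs with planted ground truth for every pipeline stage.

Real inputs to the pipeline are proteome-scale HMM hit tables, pairwise
similarity tables, a Dicer phylogeny with binary cPAZ states, and
AlphaFold structure models. The generators here emulate each of these
with known ground truth: proteomes with planted domain architectures in
each Dicer category (plus non-Dicer decoy proteins and above-threshold
decoy hits), similarity tables with planted clusters, binary characters
evolved under the two-state ER Mk process on random birth trees, and toy
PDB structures with planted CA anchor coordinates and pLDDT values.

Everything is driven by a single integer seed and is fully
deterministic. Sequences, when requested, are i.i.d. uniform over the 20
amino acids — the classifier uses only coordinates and lengths, never
sequence content. Decoy hits are placed so they never overlap planted
segments, keeping classifier ground truth unambiguous.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .domain_hits import DOMAIN_LABELS

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: truth-table category labels
CATEGORY_LABELS = ("canonical", "A", "B", "C", "D", "E", "non_dcr")

#: map generator categories onto classifier output labels
CATEGORY_TO_CLASSIFIER = {
    "canonical": "canonical", "A": "nonA", "B": "nonB", "C": "nonC",
    "D": "nonD", "E": "nonE", "non_dcr": "none",
}

#: ordered full domain complement of a canonical Dicer
_CANONICAL_ORDER = ("DEAD", "ResIII", "HeliC", "DUF283", "PAZ",
                    "RNaseIII", "RNaseIII", "dsRBD")

#: domains removed from the canonical layout per category
_REMOVED: dict[str, frozenset] = {
    "canonical": frozenset(),
    "A": frozenset({"dsRBD"}),
    "B": frozenset({"PAZ"}),
    "C": frozenset({"DEAD", "ResIII", "HeliC", "dsRBD"}),
    "D": frozenset({"PAZ", "dsRBD"}),
    # E: three or more units undetected; keep only DUF283 + tandem RNase III
    "E": frozenset({"DEAD", "ResIII", "HeliC", "PAZ", "dsRBD"}),
}

#: plausible per-domain length ranges (aa), uniform draw
_DOMAIN_LENGTHS = {
    "DEAD": (150, 200), "ResIII": (120, 170), "HeliC": (80, 130),
    "DUF283": (60, 100), "PAZ": (90, 130), "RNaseIII": (70, 110),
    "dsRBD": (60, 80),
}

_LABEL_TO_PFAM = {
    "DEAD": "PF00270.30", "ResIII": "PF04851.16", "HeliC": "PF00271.32",
    "DUF283": "PF03368.15", "PAZ": "PF02170.23", "RNaseIII": "PF00636.27",
    "dsRBD": "PF00035.27",
}

#: default category mix: the survey's observed Dicer category shares,
#: scaled to 85 % of proteins, with 15 % non-Dicer decoy proteins
DEFAULT_CATEGORY_MIX = {
    "canonical": 0.010, "A": 0.023, "B": 0.104, "C": 0.080,
    "D": 0.533, "E": 0.100, "non_dcr": 0.150,
}

_PHYLA = ("Ascomycota", "Basidiomycota", "Mucoromycota",
          "Chytridiomycota", "Zoopagomycota", "Microsporidia")
_PHYLUM_WEIGHTS = (0.55, 0.25, 0.10, 0.04, 0.03, 0.03)


@dataclass
class ArchitectureSpec:
    """One planted protein: its category and exact domain layout."""

    protein_id: str
    category_label: str
    protein_length: int
    domain_layout: list[tuple[str, int, int]]  # (label, start, end), sorted
    noise_evalue_hits: int = 0
    species: str = ""
    phylum: str = ""

    def __post_init__(self) -> None:
        if self.category_label not in CATEGORY_LABELS:
            raise ValueError(f"unknown category {self.category_label!r}")
        prev_end = 0
        for label, start, end in self.domain_layout:
            if label not in DOMAIN_LABELS:
                raise ValueError(f"unknown domain {label!r}")
            if not (1 <= start <= end <= self.protein_length):
                raise ValueError(
                    f"{self.protein_id}: segment {label} {start}-{end} outside "
                    f"1..{self.protein_length}"
                )
            if start <= prev_end:
                raise ValueError(f"{self.protein_id}: overlapping/unsorted segments")
            prev_end = end


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; the seed fully determines output."""

    seed: int = 0
    n_proteins: int = 500
    category_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    tree_tips: int = 200
    mk_rate_q: float = 0.5
    cluster_plan: list[tuple[int, float, float]] = field(
        default_factory=lambda: [(12, 72.0, 25.0), (8, 65.0, 25.0),
                                 (5, 58.0, 25.0), (3, 55.0, 25.0)])
    decoy_hit_mean: float = 0.6  # Poisson mean of >threshold noise hits/protein

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.mk_rate_q < 0:
            raise ValueError("mk_rate_q must be non-negative")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix sums to {total}, expected 1")
        for cat in self.category_mix:
            if cat not in CATEGORY_LABELS:
                raise ValueError(f"unknown category {cat!r} in mix")


def _plant_layout(category: str, rng: np.random.Generator
                  ) -> tuple[list[tuple[str, int, int]], int]:
    """Domain layout and protein length for one protein of a category."""
    if category == "non_dcr":
        # fails the gate either way: single RNase III + dsRBD, or a bare
        # tandem pair with no RNA-binding domain
        order = (("RNaseIII", "dsRBD") if rng.random() < 0.5
                 else ("RNaseIII", "RNaseIII"))
    else:
        order = tuple(d for d in _CANONICAL_ORDER if d not in _REMOVED[category])
    pos = int(rng.integers(5, 300))  # N-terminal lead
    layout = []
    for label in order:
        lo, hi = _DOMAIN_LENGTHS[label]
        length = int(rng.integers(lo, hi + 1))
        layout.append((label, pos + 1, pos + length))
        pos += length + int(rng.integers(10, 120))  # inter-domain linker
    tail = int(rng.integers(5, 250))
    protein_length = layout[-1][2] + tail
    return layout, protein_length


def generate_proteome(config: SimulationConfig) -> list[ArchitectureSpec]:
    """Plant ``n_proteins`` architectures according to the category mix.

    Proteins are grouped into synthetic proteomes (species) of one to
    three proteins each; each proteome is assigned a phylum.
    """
    rng = np.random.default_rng(config.seed)
    cats = list(config.category_mix)
    probs = np.array([config.category_mix[c] for c in cats])
    drawn = rng.choice(len(cats), size=config.n_proteins, p=probs)

    specs: list[ArchitectureSpec] = []
    species_idx, left_in_species = 0, 0
    species, phylum = "", ""
    for i, ci in enumerate(drawn):
        if left_in_species == 0:
            species_idx += 1
            left_in_species = int(rng.integers(1, 4))
            species = f"species_{species_idx:04d}"
            phylum = _PHYLA[rng.choice(len(_PHYLA), p=_PHYLUM_WEIGHTS)]
        left_in_species -= 1
        category = cats[ci]
        layout, length = _plant_layout(category, rng)
        specs.append(
            ArchitectureSpec(
                protein_id=f"prot_{i:05d}",
                category_label=category,
                protein_length=length,
                domain_layout=layout,
                noise_evalue_hits=int(rng.poisson(config.decoy_hit_mean)),
                species=species,
                phylum=phylum,
            )
        )
    return specs


def _decoy_positions(spec: ArchitectureSpec, n: int,
                     rng: np.random.Generator) -> list[tuple[int, int]]:
    """Up to ``n`` decoy segments in gaps, never overlapping planted ones."""
    gaps = []
    prev_end = 0
    for _, start, end in spec.domain_layout:
        if start - prev_end - 1 >= 40:
            gaps.append((prev_end + 1, start - 1))
        prev_end = end
    if spec.protein_length - prev_end >= 40:
        gaps.append((prev_end + 1, spec.protein_length))
    out = []
    for _ in range(n):
        if not gaps:
            break
        lo, hi = gaps[int(rng.integers(len(gaps)))]
        width = int(rng.integers(20, min(35, hi - lo) + 1))
        start = int(rng.integers(lo, hi - width + 2))
        out.append((start, start + width - 1))
    return out


def generate_hit_table(config: SimulationConfig
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hit table + truth table for a planted synthetic proteome.

    The hit table (protein_id, domain_label, start, end, evalue, score)
    holds one strong hit (E-value << 1e-3) per planted segment plus the
    planted number of decoy hits per protein, all with E-value > 1e-3 so
    the standard filter removes them. The truth table maps protein_id to
    its planted category, length, species and phylum.
    """
    specs = generate_proteome(config)
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for spec in specs:
        for label, start, end in spec.domain_layout:
            rows.append(
                {
                    "protein_id": spec.protein_id,
                    "domain_label": label,
                    "start": start,
                    "end": end,
                    "evalue": 10.0 ** -rng.uniform(5.0, 30.0),
                    "score": float(np.round(rng.uniform(30.0, 300.0), 1)),
                }
            )
        for start, end in _decoy_positions(spec, spec.noise_evalue_hits, rng):
            rows.append(
                {
                    "protein_id": spec.protein_id,
                    "domain_label": DOMAIN_LABELS[int(rng.integers(len(DOMAIN_LABELS)))],
                    "start": start,
                    "end": end,
                    # strictly above the 1e-3 cut-off
                    "evalue": 10.0 ** rng.uniform(-2.0, 1.0),
                    "score": float(np.round(rng.uniform(5.0, 15.0), 1)),
                }
            )
    hits = pd.DataFrame(rows, columns=["protein_id", "domain_label", "start",
                                       "end", "evalue", "score"])
    truth = pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in specs],
            "category": [s.category_label for s in specs],
            "protein_length": [s.protein_length for s in specs],
            "species": [s.species for s in specs],
            "phylum": [s.phylum for s in specs],
            "noise_evalue_hits": [s.noise_evalue_hits for s in specs],
        }
    )
    return hits, truth


def generate_fasta(truth: pd.DataFrame, seed: int) -> dict[str, str]:
    """I.i.d.-uniform amino-acid sequences matching the truth lengths."""
    rng = np.random.default_rng(seed + 2)
    alphabet = np.array(list(AMINO_ACIDS))
    return {
        row.protein_id: "".join(rng.choice(alphabet, size=int(row.protein_length)))
        for row in truth.itertuples(index=False)
    }


def write_fasta(sequences: Mapping[str, str], stream: TextIO) -> None:
    for pid in sequences:
        stream.write(f">{pid}\n")
        seq = sequences[pid]
        for i in range(0, len(seq), 60):
            stream.write(seq[i:i + 60] + "\n")


def write_domtblout(hits: pd.DataFrame, protein_lengths: Mapping[str, int],
                    stream: TextIO) -> None:
    """Emit hits as a HMMER-3 ``--domtblout``-dialect table.

    Envelope coordinates equal the planted coordinates; alignment
    coordinates are written equal to the envelope.
    """
    stream.write("# --- full sequence --- -------------- this domain --------------\n")
    stream.write("# target name, accession, tlen, query name, accession, qlen, ...\n")
    per_protein: dict[str, int] = {}
    for row in hits.itertuples(index=False):
        per_protein[row.protein_id] = per_protein.get(row.protein_id, 0) + 1
    seen: dict[str, int] = {}
    for row in hits.itertuples(index=False):
        seen[row.protein_id] = seen.get(row.protein_id, 0) + 1
        acc = _LABEL_TO_PFAM[row.domain_label]
        tlen = protein_lengths[row.protein_id]
        qlen = row.end - row.start + 1
        stream.write(
            f"{row.protein_id} - {tlen} {row.domain_label} {acc} {qlen} "
            f"{row.evalue:.2g} {row.score:.1f} 0.1 "
            f"{seen[row.protein_id]} {per_protein[row.protein_id]} "
            f"{row.evalue:.2g} {row.evalue:.2g} {row.score:.1f} 0.1 "
            f"1 {qlen} {row.start} {row.end} {row.start} {row.end} 0.95 -\n"
        )


# ---------------------------------------------------------------------------
# trees and binary characters


def random_yule_tree(n_tips: int, seed: int,
                     birth_rate: float = 1.0) -> dendropy.Tree:
    """Random pure-birth tree with ``n_tips`` extant tips.

    With unit birth rate the expected total branch length is about
    ``n_tips`` time units, so a character with rate q accrues on the
    order of ``q * n_tips`` expected state changes — enough signal for
    rate-recovery experiments at moderate tip counts.
    """
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0,
        num_extant_tips=n_tips, rng=random.Random(seed),
    )
    tree.is_rooted = True
    return tree


def flip_probability(q: float, t: float) -> float:
    """Per-branch state-flip probability of the two-state ER chain."""
    return 0.5 * (1.0 - np.exp(-2.0 * q * t))


def simulate_binary_character(tree: dendropy.Tree | str, q: float, seed: int,
                              include_internal: bool = False):
    """Evolve a binary character under ER-Mk down a rooted tree.

    The root state is uniform on {0, 1}; along each branch of length t
    the state flips with probability (1 - exp(-2 q t)) / 2. Returns the
    tip-state map (tip label -> 0/1); with ``include_internal`` also a
    second map keyed by the node's postorder index label (``node_<i>``),
    matching the labels used by the ancestral-reconstruction output.
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(seed)
    postorder = list(tree.postorder_node_iter())
    order = {id(n): i for i, n in enumerate(postorder)}
    states: dict[int, int] = {}
    tip_states: dict[str, int] = {}
    internal: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state = int(rng.integers(2))
        else:
            state = states[id(node.parent_node)]
            t = node.edge.length or 0.0
            if t < 0:
                raise ValueError("negative branch length")
            if rng.random() < flip_probability(q, t):
                state = 1 - state
        states[id(node)] = state
        if node.is_leaf():
            tip_states[node.taxon.label if node.taxon else f"tip_{order[id(node)]}"] = state
        else:
            label = node.label if node.label else f"node_{order[id(node)]}"
            internal[label] = state
    if include_internal:
        return tip_states, internal
    return tip_states


# ---------------------------------------------------------------------------
# similarity tables with planted clusters


def generate_similarity_table(
    cluster_plan: Sequence[tuple[int, float, float]], seed: int,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """All-vs-all pairwise similarity rows with planted clusters.

    Each plan entry (size, within_identity, between_identity) plants one
    cluster: within-cluster pairs get identity jittered upward from
    ``within_identity`` and between-cluster pairs downward from the
    larger of the two clusters' ``between_identity``. Coverage is drawn
    in 85-95 % for all pairs, so the identity threshold alone separates
    the planted clusters. A sprinkle of self-hits and reciprocal
    duplicate rows exercises table cleaning. Returns the row table and
    the planted node -> cluster-index assignment.
    """
    rng = np.random.default_rng(seed)
    nodes: list[str] = []
    planted: dict[str, int] = {}
    between_of: dict[str, float] = {}
    for ci, (size, _within, between) in enumerate(cluster_plan, start=1):
        for j in range(size):
            name = f"c{ci}_n{j:02d}"
            nodes.append(name)
            planted[name] = ci
            between_of[name] = between
    within_of = {ci: w for ci, (_s, w, _b) in enumerate(cluster_plan, start=1)}
    rows = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            cov_a = float(rng.uniform(85.0, 95.0))
            cov_b = float(rng.uniform(85.0, 95.0))
            if planted[a] == planted[b]:
                identity = within_of[planted[a]] + float(rng.uniform(0.0, 4.0))
            else:
                base = max(between_of[a], between_of[b])
                identity = base - float(rng.uniform(0.0, 4.0))
            rows.append((a, b, round(min(identity, 100.0), 2),
                         round(cov_a, 2), round(cov_b, 2)))
            if rng.random() < 0.15:  # reciprocal duplicate, slightly lower
                rows.append((b, a, round(max(min(identity, 100.0) - 1.0, 0.0), 2),
                             round(cov_b, 2), round(cov_a, 2)))
    for name in nodes:
        if rng.random() < 0.2:  # self-hit
            rows.append((name, name, 100.0, 100.0, 100.0))
    table = pd.DataFrame(rows, columns=["id_a", "id_b", "identity",
                                        "coverage_a", "coverage_b"])
    return table, planted


# ---------------------------------------------------------------------------
# toy structure models


@dataclass(frozen=True)
class SegmentPlan:
    """A named residue segment with a 3-D anchor for its first residue.

    Residues after the first are laid out from the anchor along
    ``direction`` at ``spacing`` Å per residue (a straight pseudo-chain;
    realism is not the point, planted distances are).
    """

    label: str
    start: int
    end: int
    anchor: tuple[float, float, float]
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    spacing: float = 3.8


def generate_toy_structure(
    segments: Sequence[SegmentPlan],
    plddt_plan: float | Mapping[str, float] = 80.0,
    chain: str = "A",
) -> str:
    """PDB text with one CA atom per residue and planted pLDDT B-factors.

    ``plddt_plan`` is either one value for all residues or a map from
    segment label to value. Segments must be sorted and non-overlapping.
    """
    if not segments:
        raise ValueError("need at least one segment")
    prev_end = 0
    for seg in segments:
        if seg.start <= prev_end:
            raise ValueError("segments must be sorted and non-overlapping")
        prev_end = seg.end
    lines = []
    serial = 0
    for seg in segments:
        direction = np.asarray(seg.direction, dtype=float)
        norm = np.linalg.norm(direction)
        if norm == 0:
            raise ValueError(f"{seg.label}: zero direction vector")
        direction /= norm
        anchor = np.asarray(seg.anchor, dtype=float)
        if isinstance(plddt_plan, Mapping):
            if seg.label not in plddt_plan:
                raise ValueError(f"no pLDDT planned for segment {seg.label!r}")
            plddt = float(plddt_plan[seg.label])
        else:
            plddt = float(plddt_plan)
        for k, res in enumerate(range(seg.start, seg.end + 1)):
            serial += 1
            x, y, z = anchor + k * seg.spacing * direction
            lines.append(
                f"ATOM  {serial:>5}  CA  ALA {chain}{res:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{plddt:6.2f}"
                f"           C  "
            )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
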