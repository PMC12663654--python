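"""End-to-end orchestration of the Dicer survey stages.

``run_all`` drives: hit-table parsing and E-value filtering, architecture
assembly, Dicer gating and six-category classification, summary tables,
PAZ/fPAZ region extraction, optional sequence-similarity clustering and
optional ER-Mk ancestral reconstruction. Inputs are either supplied as
files or generated synthetically with planted truth; every run writes a
manifest with input hashes and the thresholds used, and identical
configs produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from io import StringIO
from pathlib import Path

import pandas as pd

from . import dcr_classifier, domain_hits, mk_ace, paz_regions
from . import similarity_networks as simnet
from . import synthetic_data


@dataclass
class RunConfig:
    """Paths, thresholds and the seed of one pipeline run."""

    out_dir: str = "run"
    hits_path: str | None = None       # domtblout or 6-column TSV
    meta_path: str | None = None       # protein metadata TSV
    fasta_path: str | None = None
    pairs_path: str | None = None      # sequence-similarity pair TSV
    tree_path: str | None = None       # rooted Newick
    states_path: str | None = None     # tip-state TSV (id, 0/1)
    evalue_max: float = domain_hits.DEFAULT_EVALUE_MAX
    identity_min: float = simnet.DEFAULT_IDENTITY_MIN
    coverage_min: float = simnet.DEFAULT_COVERAGE_MIN
    tm_min: float = simnet.DEFAULT_TM_MIN
    plddt_min: float = simnet.DEFAULT_PLDDT_MIN
    seed: int = 0
    simulate_n: int = 0                # > 0: generate synthetic inputs first
    tree_tips: int = 200
    mk_rate_q: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.evalue_max):
            raise ValueError("evalue_max must be positive")
        for name in ("identity_min", "coverage_min"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} outside [0, 100]")
        if not 0 <= self.tm_min <= 1:
            raise ValueError("tm_min outside [0, 1]")

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items() if v is not None]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = cls.__dataclass_fields__
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            target = types[key].type
            if "int" in target:
                kwargs[key] = int(value)
            elif "float" in target:
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


class StageError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_synthetic_inputs(sim: synthetic_data.SimulationConfig,
                           inputs_dir: Path) -> dict[str, Path]:
    """Generate every synthetic pipeline input into ``inputs_dir``.

    Writes a domtblout hit table, metadata/truth TSV, FASTA, pairwise
    similarity table with its planted clustering, a random tree and an
    ER-simulated tip-state table. Returns the path of each artifact.
    """
    inputs_dir = Path(inputs_dir)
    inputs_dir.mkdir(parents=True, exist_ok=True)
    hits, truth = synthetic_data.generate_hit_table(sim)
    lengths = dict(zip(truth.protein_id, truth.protein_length))
    with open(inputs_dir / "hits.domtblout", "w") as fh:
        synthetic_data.write_domtblout(hits, lengths, fh)
    truth.to_csv(inputs_dir / "meta.tsv", sep="\t", index=False)
    sequences = synthetic_data.generate_fasta(truth, sim.seed)
    with open(inputs_dir / "proteins.fasta", "w") as fh:
        synthetic_data.write_fasta(sequences, fh)
    pairs, planted = synthetic_data.generate_similarity_table(
        sim.cluster_plan, sim.seed)
    pairs.to_csv(inputs_dir / "pairs.tsv", sep="\t", index=False, header=False)
    pd.DataFrame(sorted(planted.items()), columns=["id", "cluster"]).to_csv(
        inputs_dir / "planted_clusters.tsv", sep="\t", index=False)
    tree = synthetic_data.random_yule_tree(sim.tree_tips, sim.seed)
    (inputs_dir / "tree.nwk").write_text(
        tree.as_string(schema="newick", suppress_rooting=True))
    states = synthetic_data.simulate_binary_character(
        tree, sim.mk_rate_q, sim.seed + 3)
    with open(inputs_dir / "tip_states.tsv", "w") as fh:
        fh.write("protein_id\tstate\n")
        for tip in sorted(states):
            fh.write(f"{tip}\t{states[tip]}\n")
    return {
        "hits": inputs_dir / "hits.domtblout",
        "meta": inputs_dir / "meta.tsv",
        "fasta": inputs_dir / "proteins.fasta",
        "pairs": inputs_dir / "pairs.tsv",
        "planted_clusters": inputs_dir / "planted_clusters.tsv",
        "tree": inputs_dir / "tree.nwk",
        "states": inputs_dir / "tip_states.tsv",
    }


def _attach_synthetic_inputs(config: RunConfig, inputs_dir: Path) -> None:
    sim = synthetic_data.SimulationConfig(
        seed=config.seed, n_proteins=config.simulate_n,
        tree_tips=config.tree_tips, mk_rate_q=config.mk_rate_q,
    )
    paths = write_synthetic_inputs(sim, inputs_dir)
    config.hits_path = str(paths["hits"])
    config.meta_path = str(paths["meta"])
    config.fasta_path = str(paths["fasta"])
    config.pairs_path = str(paths["pairs"])
    config.tree_path = str(paths["tree"])
    config.states_path = str(paths["states"])


def _require(path_str: str | None, stage: str) -> Path:
    if path_str is None:
        raise StageError(f"stage {stage}: required input path not configured")
    path = Path(path_str)
    if not path.exists():
        raise StageError(f"stage {stage}: input file not found: {path}")
    return path


def run_all(config: RunConfig) -> Path:
    """Run every configured stage; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate_n > 0 and config.hits_path is None:
        _attach_synthetic_inputs(config, out / "inputs")

    # --- classify ---------------------------------------------------------
    hits_file = _require(config.hits_path, "classify")
    meta_file = _require(config.meta_path, "classify")
    with open(hits_file) as fh:
        head = fh.read(2048)
    parser = (domain_hits.parse_hits_tsv if head.startswith("protein_id")
              else domain_hits.parse_domtblout)
    with open(hits_file) as fh:
        try:
            hits = parser(fh)
        except domain_hits.MalformedRowError as exc:
            raise StageError(f"stage classify: {hits_file}: {exc}") from exc
    hits = domain_hits.filter_hits(hits, config.evalue_max)
    meta = pd.read_csv(meta_file, sep="\t")
    lengths = dict(zip(meta.protein_id, meta.protein_length))
    archs = domain_hits.assemble_all(hits, lengths)
    meta_by_id = {row.protein_id: row for row in meta.itertuples(index=False)}
    sequences = {}
    if config.fasta_path:
        from Bio import SeqIO
        with open(_require(config.fasta_path, "classify")) as fh:
            sequences = {r.id: str(r.seq) for r in SeqIO.parse(fh, "fasta")}
    records = []
    for pid in meta.protein_id:
        row = meta_by_id[pid]
        records.append(
            dcr_classifier.build_record(
                archs[pid],
                species=getattr(row, "species", None),
                phylum=getattr(row, "phylum", None),
                sequence=sequences.get(pid),
            )
        )
    frame = dcr_classifier.records_to_frame(records)
    frame.to_csv(out / "classified.tsv", sep="\t", index=False)
    summary = dcr_classifier.summarize(records)
    (out / "summary.json").write_text(json.dumps(
        {
            "counts": summary.counts,
            "percentages": summary.percentages,
            "cpaz_lacking_percent": summary.cpaz_lacking_percent,
            "total": summary.total,
        }, indent=2, sort_keys=True) + "\n")
    summary.by_phylum.to_csv(out / "by_phylum.tsv", sep="\t")

    # --- PAZ regions ------------------------------------------------------
    regions = []
    for rec in records:
        if rec.is_dcr:
            region = paz_regions.extract_paz(rec.arch, rec.sequence)
            if region is not None:
                regions.append(region)
    with open(out / "paz_regions.tsv", "w") as fh:
        paz_regions.regions_to_tsv(regions, fh)
    if sequences:
        with open(out / "paz_regions.fasta", "w") as fh:
            paz_regions.write_region_fasta(regions, sequences, fh)

    # --- sequence-similarity clustering -----------------------------------
    if config.pairs_path:
        pairs = simnet.read_pairs_tsv(
            _require(config.pairs_path, "net-seq"),
            ["id_a", "id_b", "identity", "coverage_a", "coverage_b"])
        graph = simnet.build_sequence_network(
            pairs, config.identity_min, config.coverage_min)
        clustering = simnet.connected_components(graph)
        clustering.as_frame().to_csv(out / "seq_clusters.tsv", sep="\t", index=False)

    # --- ancestral reconstruction ----------------------------------------
    if config.tree_path or config.states_path:
        tree_file = _require(config.tree_path, "ace")
        states_file = _require(config.states_path, "ace")
        with open(states_file) as fh:
            states = mk_ace.read_tip_states(fh)
        pc = mk_ace.PhyloCharacter(tree_file.read_text(), states)
        ace = mk_ace.ancestral_reconstruction(pc)
        (out / "ace.json").write_text(json.dumps(
            {
                "q_hat": ace.q_hat,
                "log_likelihood": ace.log_likelihood,
                "at_lower_bound": ace.at_lower_bound,
            }, indent=2, sort_keys=True) + "\n")
        (out / "ace_marginals.tsv").write_text(
            mk_ace.marginals_to_tsv(ace.node_marginals))

    # --- manifest ---------------------------------------------------------
    try:
        pkg_version = version("dicer-atlas")
    except PackageNotFoundError:
        pkg_version = "unknown"
    manifest = {
        "version": pkg_version,
        "seed": config.seed,
        "thresholds": {
            "evalue_max": config.evalue_max,
            "identity_min": config.identity_min,
            "coverage_min": config.coverage_min,
            "tm_min": config.tm_min,
            "plddt_min": config.plddt_min,
        },
        "inputs": {
            name: _sha256(Path(p))
            for name, p in (
                ("hits", config.hits_path), ("meta", config.meta_path),
                ("fasta", config.fasta_path), ("pairs", config.pairs_path),
                ("tree", config.tree_path), ("states", config.states_path),
            ) if p and Path(p).exists()
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def summary_text(summary: dcr_classifier.CategorySummary) -> str:
    """Human-readable category summary block."""
    buf = StringIO()
    buf.write(f"{'category':<12}{'count':>8}{'percent':>9}\n")
    for cat in dcr_classifier.CATEGORIES:
        buf.write(f"{cat:<12}{summary.counts[cat]:>8}"
                  f"{summary.percentages[cat]:>9.1f}\n")
    buf.write(f"{'total':<12}{summary.total:>8}\n")
    buf.write(f"cPAZ-lacking (B+D+E): {summary.cpaz_lacking_percent:.1f} %\n")
    return buf.getvalue()
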