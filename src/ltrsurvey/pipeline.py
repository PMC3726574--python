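"""Pipeline orchestration: simulate -> detect -> solo -> capture -> evolve
-> profile, from a single declarative config.

Each stage reads standard-format files written by its upstream stages, so
stages can also be run individually against externally produced inputs.
A manifest records the config hash, per-stage input/output checksums and
wall-clock times; re-running with an unchanged config skips stages whose
inputs and outputs are intact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "detect", "solo", "capture", "evolve", "profile")


class ConfigError(ValueError):
    pass


class DependencyError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=dict)
    params: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | None = None,
                  seed: int | None = None) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            line = f" (line {mark.line + 1})" if mark else ""
            raise ConfigError(f"invalid YAML in {path}{line}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        stages = {s: True for s in STAGE_ORDER}
        stages.update({k: bool(v) for k, v in (raw.get("stages") or {}).items()})
        unknown = set(stages) - set(STAGE_ORDER)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        params = {s: dict(raw.get(s) or {}) for s in STAGE_ORDER}
        for s, block in params.items():
            if not isinstance(block, dict):
                raise ConfigError(f"stage block '{s}' must be a mapping")
        return cls(
            outdir=Path(outdir or raw.get("outdir", "ltrsurvey_out")),
            seed=int(seed if seed is not None else raw.get("seed", 0)),
            stages=stages, params=params)

    def stage_seed(self, stage: str) -> int:
        return self.seed + STAGE_ORDER.index(stage)

    def content_hash(self) -> str:
        body = json.dumps({"seed": self.seed, "stages": self.stages,
                           "params": self.params}, sort_keys=True, default=str)
        return hashlib.sha256(body.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config_hash": self.config_hash, "version": self.version,
             "stages": self.stages}, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: Path) -> "RunManifest | None":
        if not path.exists():
            return None
        data = json.loads(path.read_text())
        return cls(config_hash=data.get("config_hash", ""),
                   version=data.get("version", ""),
                   stages=data.get("stages", {}))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


# stage output filenames
FILES = {
    "genome": "genome.fasta",
    "truth_gff": "truth.gff3",
    "truth_tsv": "truth.tsv",
    "cds": "cds.fasta",
    "protein": "protein.fasta",
    "elements_tsv": "elements.tsv",
    "elements_gff": "elements.gff3",
    "solos_bed": "solos.bed",
    "solos_tsv": "solos.tsv",
    "captured": "captured_genes.tsv",
    "pseudogenes": "pseudogenes.tsv",
    "kaks": "kaks.tsv",
    "density": "density.bedgraph",
    "summary_tsv": "summary.tsv",
    "report_txt": "report.txt",
}

STAGE_IO = {
    "simulate": ([], ["genome", "truth_gff", "truth_tsv", "cds", "protein"]),
    "detect": (["genome"], ["elements_tsv", "elements_gff"]),
    "solo": (["genome", "elements_tsv"], ["solos_bed", "solos_tsv"]),
    "capture": (["genome", "truth_gff", "elements_tsv", "cds"],
                ["captured", "pseudogenes"]),
    "evolve": (["genome", "elements_tsv", "captured", "cds"], ["kaks"]),
    "profile": (["genome", "elements_tsv"],
                ["density", "summary_tsv", "report_txt"]),
}


def run(config_path: str | Path, outdir: str | None = None,
        seed: int | None = None, only: list[str] | None = None
        ) -> RunManifest:
    """Execute the enabled stages in dependency order.

    Stages whose config, inputs and outputs are unchanged since the last
    run are skipped. `only` restricts execution to the named stages
    (their inputs must already exist).
    """
    from . import __version__

    cfg = PipelineConfig.from_yaml(config_path, outdir, seed)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = cfg.outdir / "manifest.json"
    previous = RunManifest.load(manifest_path)
    manifest = RunManifest(config_hash=cfg.content_hash(), version=__version__)

    for stage in STAGE_ORDER:
        enabled = cfg.stages.get(stage, True)
        if only is not None:
            enabled = stage in only
        if not enabled:
            continue
        needs, makes = STAGE_IO[stage]
        missing = [n for n in needs
                   if not (cfg.outdir / FILES[n]).exists()]
        if missing:
            raise DependencyError(
                f"stage '{stage}' requires {[FILES[m] for m in missing]}; "
                f"run the upstream stage first")
        in_sums = {n: _sha256(cfg.outdir / FILES[n]) for n in needs}
        if _can_skip(previous, manifest, stage, cfg, in_sums):
            manifest.stages[stage] = dict(previous.stages[stage],
                                          skipped=True)
            logger.info("stage %s: unchanged, skipped", stage)
            continue
        t0 = time.time()
        _STAGE_FUNCS[stage](cfg)
        out_sums = {}
        for n in makes:
            path = cfg.outdir / FILES[n]
            if path.exists():
                out_sums[n] = _sha256(path)
        manifest.stages[stage] = {
            "inputs": in_sums, "outputs": out_sums,
            "seconds": round(time.time() - t0, 2), "skipped": False}
        logger.info("stage %s: %.1fs", stage,
                    manifest.stages[stage]["seconds"])
    manifest.save(manifest_path)
    return manifest


def _can_skip(previous: RunManifest | None, current: RunManifest,
              stage: str, cfg: PipelineConfig, in_sums: dict) -> bool:
    if previous is None or previous.config_hash != current.config_hash:
        return False
    prev = previous.stages.get(stage)
    if not prev or prev.get("inputs") != in_sums:
        return False
    for name, checksum in prev.get("outputs", {}).items():
        path = cfg.outdir / FILES[name]
        if not path.exists() or _sha256(path) != checksum:
            return False
    return bool(prev.get("outputs"))


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: PipelineConfig) -> None:
    from .simulate import (SimulationConfig, simulate_genome,
                           write_gene_fastas, write_genome_fasta,
                           write_truth_gff3, write_truth_tsv)

    params = dict(cfg.params.get("simulate", {}))
    params.setdefault("seed", cfg.stage_seed("simulate"))
    sim_cfg = SimulationConfig(**params)
    genome, truth = simulate_genome(sim_cfg)
    write_genome_fasta(genome, cfg.outdir / FILES["genome"], sim_cfg.chrom)
    write_truth_gff3(truth, cfg.outdir / FILES["truth_gff"])
    write_truth_tsv(truth, cfg.outdir / FILES["truth_tsv"])
    write_gene_fastas(truth, cfg.outdir / FILES["cds"],
                      cfg.outdir / FILES["protein"])


def _load_genome(cfg: PipelineConfig) -> dict[str, str]:
    from .simulate import read_genome_fasta
    return read_genome_fasta(cfg.outdir / FILES["genome"])


def _stage_detect(cfg: PipelineConfig) -> None:
    from .detect import (DetectionParams, detect, write_elements_gff3,
                         write_elements_tsv)

    params = DetectionParams(**cfg.params.get("detect", {}))
    elements = []
    for chrom, seq in _load_genome(cfg).items():
        elements.extend(detect(seq, params, chrom))
    write_elements_tsv(elements, cfg.outdir / FILES["elements_tsv"])
    write_elements_gff3(elements, cfg.outdir / FILES["elements_gff"])


def _stage_solo(cfg: PipelineConfig) -> None:
    from .detect import read_elements_tsv
    from .solo import find_solos, write_solos_bed, write_solos_tsv

    params = cfg.params.get("solo", {})
    elements = read_elements_tsv(cfg.outdir / FILES["elements_tsv"])
    solos = []
    for chrom, seq in _load_genome(cfg).items():
        chrom_elements = [e for e in elements if e.chrom == chrom]
        solos.extend(find_solos(
            seq, chrom_elements, chrom,
            e_cutoff=float(params.get("e_cutoff", 1.0e-9)),
            min_identity=float(params.get("min_identity", 0.70)),
            calibrate_seed=cfg.stage_seed("solo")))
    write_solos_bed(solos, cfg.outdir / FILES["solos_bed"])
    write_solos_tsv(solos, cfg.outdir / FILES["solos_tsv"])


def _stage_capture(cfg: PipelineConfig) -> None:
    from .capture import (call_captured, classify_pseudogene, filter_te_genes,
                          load_annotation, write_captured_tsv,
                          write_pseudogene_tsv)
    from .detect import read_elements_tsv

    genome = _load_genome(cfg)
    genes = load_annotation(cfg.outdir / FILES["truth_gff"], genome,
                            cds_fasta=cfg.outdir / FILES["cds"])
    elements = read_elements_tsv(cfg.outdir / FILES["elements_tsv"])
    captured = filter_te_genes(call_captured(genes, elements), genes)
    write_captured_tsv(captured, cfg.outdir / FILES["captured"])

    # pseudogene calls for captured genes with an annotated parent gene
    by_id = {g.gene_id: g for g in genes}
    calls = []
    for cg in captured:
        gene = by_id[cg.gene_id]
        parent_id = _parent_gene_of(cfg, cg.gene_id)
        parent = by_id.get(parent_id) if parent_id else None
        if parent is None or len(parent.protein) < 50:
            continue
        calls.append(classify_pseudogene(gene.cds_seq, parent.protein,
                                         gene_id=cg.gene_id,
                                         parent_gene_id=parent_id))
    write_pseudogene_tsv(calls, cfg.outdir / FILES["pseudogenes"])


def _parent_gene_of(cfg: PipelineConfig, gene_id: str) -> str | None:
    """Parent-gene link from the truth annotation, when present."""
    path = cfg.outdir / FILES["truth_gff"]
    if not path.exists():
        return None
    for line in path.read_text().splitlines():
        if "\tgene\t" not in line:
            continue
        attrs = dict(kv.split("=", 1)
                     for kv in line.split("\t")[8].split(";") if "=" in kv)
        if attrs.get("ID") == gene_id:
            return attrs.get("parent_gene")
    return None


def _stage_evolve(cfg: PipelineConfig) -> None:
    from .capture import call_captured, load_annotation
    from .detect import read_elements_tsv
    from .kaks import kaks_for_pair, pair_elements, pair_genes, write_kaks_tsv

    params = cfg.params.get("evolve", {})
    genome_dict = _load_genome(cfg)
    elements = read_elements_tsv(cfg.outdir / FILES["elements_tsv"])
    genes = load_annotation(cfg.outdir / FILES["truth_gff"], genome_dict,
                            cds_fasta=cfg.outdir / FILES["cds"])
    rows = []
    for chrom, seq in genome_dict.items():
        chrom_elements = [e for e in elements if e.chrom == chrom]
        eps = pair_elements(
            chrom_elements, seq,
            min_ltr_identity=float(params.get("min_ltr_identity", 0.80)))
        captured = call_captured(genes, chrom_elements)
        pairs = pair_genes(
            captured, eps, genes,
            min_protein_identity=float(params.get("min_protein_identity", 0.50)))
        by_id = {g.gene_id: g for g in genes}
        for gp in pairs:
            cds_a = by_id[gp.gene_a].cds_seq
            cds_b = by_id[gp.gene_b].cds_seq
            if len(cds_a) % 3 or len(cds_b) % 3:
                continue  # disabled copies are handled by the capture stage
            try:
                rows.append((gp.gene_a, gp.gene_b, kaks_for_pair(cds_a, cds_b)))
            except ValueError:
                continue
    write_kaks_tsv(rows, cfg.outdir / FILES["kaks"])


def _stage_profile(cfg: PipelineConfig) -> None:
    from .detect import read_elements_tsv
    from .profiling import density_profile, write_density_bedgraph

    params = cfg.params.get("profile", {})
    genome = _load_genome(cfg)
    elements = read_elements_tsv(cfg.outdir / FILES["elements_tsv"])
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    window = int(params.get("window_bp", 200_000))
    profiles = density_profile(elements, chrom_lengths, window)
    write_density_bedgraph(profiles, cfg.outdir / FILES["density"])
    report(cfg)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "detect": _stage_detect,
    "solo": _stage_solo,
    "capture": _stage_capture,
    "evolve": _stage_evolve,
    "profile": _stage_profile,
}


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def occupied_bp(spans: list[tuple[int, int]]) -> int:
    """Total genome length covered by the union of the spans."""
    total = 0
    last_end = None
    for start, end in sorted(spans):
        if last_end is None or start >= last_end:
            total += end - start
            last_end = end
        elif end > last_end:
            total += end - last_end
            last_end = end
    return total


def percent_of_genome(occupied: int, genome_length: int) -> float:
    """Occupied percentage, one decimal (0.0 for an empty genome)."""
    if genome_length <= 0:
        return 0.0
    return round(occupied / genome_length * 100, 1)


def report(cfg: PipelineConfig) -> dict:
    """Summary statistics of a run: counts, occupied bp, percentages."""
    import pandas as pd
    from .detect import read_elements_tsv

    genome = _load_genome(cfg)
    genome_length = sum(len(s) for s in genome.values())
    elements = read_elements_tsv(cfg.outdir / FILES["elements_tsv"])
    occ = occupied_bp([(e.start, e.end) for e in elements])
    stats = {
        "genome_bp": genome_length,
        "n_full_elements": len(elements),
        "occupied_bp": occ,
        "occupied_percent": percent_of_genome(occ, genome_length),
    }
    solos_path = cfg.outdir / FILES["solos_tsv"]
    if solos_path.exists():
        stats["n_solo_ltrs"] = len(pd.read_csv(solos_path, sep="\t"))
    cap_path = cfg.outdir / FILES["captured"]
    if cap_path.exists():
        cap = pd.read_csv(cap_path, sep="\t")
        stats["n_captured_genes"] = len(cap)
    ps_path = cfg.outdir / FILES["pseudogenes"]
    if ps_path.exists():
        ps = pd.read_csv(ps_path, sep="\t")
        stats["n_pseudogenes"] = (int(ps["is_pseudogene"].sum())
                                  if len(ps) else 0)
        if stats.get("n_captured_genes"):
            stats["pseudogene_percent"] = round(
                stats["n_pseudogenes"] / stats["n_captured_genes"] * 100, 1)
    kaks_path = cfg.outdir / FILES["kaks"]
    if kaks_path.exists():
        kk = pd.read_csv(kaks_path, sep="\t", na_values="NA")
        stats["n_gene_pairs"] = len(kk)
        if len(kk) and kk["ratio"].notna().any():
            stats["mean_ka_ks"] = round(float(kk["ratio"].dropna().mean()), 3)

    pd.DataFrame([stats]).to_csv(cfg.outdir / FILES["summary_tsv"],
                                 sep="\t", index=False)
    lines = ["ltrsurvey run summary", "=" * 21]
    for k, v in stats.items():
        lines.append(f"{k:24s} {v}")
    (cfg.outdir / FILES["report_txt"]).write_text("\n".join(lines) + "\n")
    return stats
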