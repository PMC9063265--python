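"""End-to-end orchestration and self-describing tab-delimited artifacts.

Each stage writes tab-delimited tables whose header comments record the
tool version, the parameters used and the seed, plus one JSON line per
stage run in ``pipeline.log.jsonl``, so every artifact is reproducible
from its own metadata.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .annotation import assign_gtrnadb_names, parse_trna_annotation
from .destats import DeParams, DesignInfo, DETable, filter_low_counts, run_de, cpm
from .genome import (
    FlankParams,
    GenomeBundle,
    PrematureRecord,
    ROLE_GENOMIC,
    ROLE_PREMATURE,
    build_bundle,
    read_fasta,
    read_registry,
    write_fasta,
    write_genes_table,
    write_registry,
)
from .preprocess import PreprocessParams, preprocess_fastq
from .quantify import (
    CountTable,
    LEVELS,
    aggregate_counts,
    combine_samples,
    quantify_reads,
)
from .viz import (
    aa_pyramid_data,
    anticodon_bar_data,
    mds_coordinates,
    plot_aa_pyramid,
    plot_anticodon_bar,
    plot_mds,
    plot_volcano,
    volcano_data,
)

import numpy as np


@dataclass
class PipelineConfig:
    genome: str = ""
    annotation: str = ""
    fastqs: list[str] = field(default_factory=list)
    sample_sheet: str = ""               # TSV: sample<TAB>group<TAB>fastq
    control_group: str | None = None     # fold-change baseline; default: first label alphabetically
    outdir: str = "trnaquant_out"
    flank_len: int = 50
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    k: int = 3
    seed: int = 1715
    len_threshold: int = 30
    min_cpm: float = 1.0
    min_fraction: float = 0.9
    de: DeParams = field(default_factory=DeParams)
    top_k: int = 500
    levels: tuple[str, ...] = LEVELS


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    for key, value in raw.items():
        if key == "preprocess":
            cfg.preprocess = PreprocessParams(**value)
        elif key == "de":
            cfg.de = DeParams(**value)
        elif hasattr(cfg, key):
            setattr(cfg, key, value)
        else:
            raise ValueError(f"unknown config field {key!r}")
    return cfg


# ---------------------------------------------------------------------------
# self-describing artifacts

def _header(params: Mapping[str, object]) -> str:
    pairs = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# trnaquant v{__version__} {pairs}\n"


def write_table(
    frame: pd.DataFrame, path: str | Path, params: Mapping[str, object],
    index_label: str = "name",
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(params))
        frame.to_csv(fh, sep="\t", index_label=index_label)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def _file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def log_stage(outdir: str | Path, stage: str, params: Mapping[str, object],
              inputs: list[str] | None = None,
              tallies: Mapping[str, object] | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entry = {
        "stage": stage,
        "version": __version__,
        "params": {k: str(v) for k, v in params.items()},
        "input_hashes": {p: _file_hash(p) for p in (inputs or []) if Path(p).exists()},
        "tallies": dict(tallies or {}),
    }
    with open(outdir / "pipeline.log.jsonl", "a") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# stages

def stage_build_genome(
    genome_path: str | Path, annotation_path: str | Path, outdir: str | Path,
    flank_len: int = 50,
) -> GenomeBundle:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(genome_path)
    with open(annotation_path) as fh:
        genes = parse_trna_annotation(fh, genome)
    genes = assign_gtrnadb_names(genes, genome)
    bundle = build_bundle(genome, genes, FlankParams(flank_len))
    write_fasta(bundle.artificial_references, outdir / "artificial_genome.fa")
    write_fasta(bundle.mature_records, outdir / "mature_genome.fa")
    write_registry(bundle.registry, outdir / "registry.tsv")
    write_genes_table(genes, outdir / "genes.tsv")
    log_stage(outdir, "build_genome", {"flank_len": flank_len},
              [str(genome_path), str(annotation_path)],
              {"n_genes": len(genes), "n_chroms": len(genome)})
    return bundle


def load_bundle(build_dir: str | Path) -> GenomeBundle:
    """Reconstruct a bundle from the build-genome stage's artifacts."""
    build_dir = Path(build_dir)
    registry = read_registry(build_dir / "registry.tsv")
    artificial = read_fasta(build_dir / "artificial_genome.fa")
    mature = read_fasta(build_dir / "mature_genome.fa")
    masked = {n: s for n, s in artificial.items()
              if registry[n].role == ROLE_GENOMIC}
    premature = [
        PrematureRecord(name=n, seq=s,
                        upstream_flank_len=registry[n].upstream_flank_len,
                        gene_len=registry[n].gene_len)
        for n, s in artificial.items() if registry[n].role == ROLE_PREMATURE
    ]
    return GenomeBundle(
        masked_chroms=masked, premature_records=premature,
        mature_records=list(mature.items()), registry=registry,
    )


def stage_preprocess(
    fastq: str | Path, outdir: str | Path, params: PreprocessParams
) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = Path(fastq).name.removesuffix(".gz").removesuffix(".fastq")
    out = outdir / f"{stem}.clean.fastq"
    report = preprocess_fastq(fastq, out, params)
    with open(outdir / f"{stem}.qc.tsv", "w") as fh:
        fh.write(_header({"stage": "preprocess", "fastq": fastq}))
        fh.write(report.to_tsv())
    log_stage(outdir, "preprocess",
              {"adapter_preset": params.adapter_preset,
               "min_quality": params.min_quality, "min_len": params.min_len},
              [str(fastq)], vars(report))
    return out


def stage_quantify(
    fastqs: Mapping[str, str | Path], bundle: GenomeBundle, outdir: str | Path,
    k: int = 3, seed: int = 1715, len_threshold: int = 30,
) -> dict[str, CountTable]:
    """Quantify each sample (name -> preprocessed FASTQ) at all three levels."""
    from .preprocess import _open_text, parse_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    per_sample = []
    tallies = {}
    for sample, path in fastqs.items():
        with _open_text(path) as fh:
            reads = [(r.read_id, r.seq) for r in parse_fastq(fh)]
        table, tally, drop = quantify_reads(
            reads, bundle, k=k, seed=seed, len_threshold=len_threshold,
            sample=sample,
        )
        per_sample.append(table)
        tallies[sample] = vars(tally)
    individual = combine_samples(per_sample)
    tables = {"individual": individual}
    for level in ("isodecoder", "isoacceptor"):
        tables[level] = aggregate_counts(individual, level)
    params = {"k": k, "seed": seed, "len_threshold": len_threshold}
    for level, table in tables.items():
        write_table(table.counts, outdir / f"counts_{level}.tsv", params)
    pd.DataFrame(tallies).T.to_csv(outdir / "class_tally.tsv", sep="\t",
                                   index_label="sample")
    log_stage(outdir, "quantify", params, [str(p) for p in fastqs.values()],
              {s: t["n_counted_r2"] for s, t in tallies.items()})
    return tables


def stage_filter(
    table: CountTable, outdir: str | Path,
    min_cpm: float = 1.0, min_fraction: float = 0.9,
) -> CountTable:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kept, removed = filter_low_counts(table, min_cpm, min_fraction)
    params = {"min_cpm": min_cpm, "min_fraction": min_fraction,
              "level": table.level}
    write_table(kept.counts, outdir / f"counts_{table.level}.filtered.tsv", params)
    log_stage(outdir, "filter", params, [],
              {"kept": len(kept.entities), "removed": len(removed)})
    return kept


def stage_de(
    table: CountTable, design: DesignInfo, outdir: str | Path, params: DeParams
) -> DETable:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    de = run_de(table, design, params)
    meta = {"level": table.level, "fc_threshold": params.fc_threshold,
            "alpha": params.alpha, "adjust": params.adjust}
    write_table(de.table, outdir / f"de_{table.level}.tsv", meta)
    log_stage(outdir, "de", meta, [],
              {"significant": int(de.table["significant"].sum())})
    return de


def stage_plot(
    de_tables: Mapping[str, DETable], filtered: CountTable,
    design: DesignInfo, outdir: str | Path,
    fc_threshold: float = 1.5, alpha: float = 0.05, top_k: int = 500,
) -> dict[str, pd.DataFrame]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data: dict[str, pd.DataFrame] = {}
    log2cpm = np.log2(cpm(filtered) + 0.5)
    if filtered.counts.shape[1] >= 3:
        mds = mds_coordinates(log2cpm, top_k=top_k)
        data["mds"] = mds.coordinates
        write_table(mds.coordinates, outdir / "mds.tsv",
                    {"top_k": top_k}, index_label="sample")
        groups = dict(zip(design.samples, design.groups))
        plot_mds(mds, groups, str(outdir / "mds.png"))
    if "individual" in de_tables:
        volcano = volcano_data(de_tables["individual"], fc_threshold, alpha)
        data["volcano"] = volcano
        write_table(volcano, outdir / "volcano.tsv", {"alpha": alpha})
        plot_volcano(volcano, str(outdir / "volcano.png"))
    if "isodecoder" in de_tables:
        bars = anticodon_bar_data(de_tables["isodecoder"])
        data["anticodon_bar"] = bars
        write_table(bars, outdir / "anticodon_bar.tsv", {}, index_label="anticodon")
        plot_anticodon_bar(bars, str(outdir / "anticodon_bar.png"))
    if "isoacceptor" in de_tables:
        pyramid = aa_pyramid_data(de_tables["isoacceptor"])
        data["aa_pyramid"] = pyramid
        write_table(pyramid, outdir / "aa_pyramid.tsv", {}, index_label="amino_acid")
        plot_aa_pyramid(pyramid, str(outdir / "aa_pyramid.png"))
    log_stage(outdir, "plot", {"top_k": top_k}, [], {})
    return data


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """TSV with columns sample, group, fastq (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if list(df.iloc[0])[:2] == ["sample", "group"]:
        df = df.iloc[1:].reset_index(drop=True)
    df.columns = ["sample", "group", "fastq"][: df.shape[1]]
    return df


def run_all(cfg: PipelineConfig) -> dict[str, object]:
    """Chain all stages: build genome -> preprocess -> quantify -> filter ->
    DE -> plot data.  Returns the in-memory artifacts keyed by stage."""
    outdir = Path(cfg.outdir)
    bundle = stage_build_genome(cfg.genome, cfg.annotation,
                                outdir / "genome", cfg.flank_len)
    sheet = read_sample_sheet(cfg.sample_sheet)
    cleaned: dict[str, Path] = {}
    for _, row in sheet.iterrows():
        cleaned[row["sample"]] = stage_preprocess(
            row["fastq"], outdir / "preprocess", cfg.preprocess
        )
    tables = stage_quantify(cleaned, bundle, outdir / "counts",
                            k=cfg.k, seed=cfg.seed,
                            len_threshold=cfg.len_threshold)
    design = DesignInfo(samples=tuple(sheet["sample"]),
                        groups=tuple(sheet["group"]),
                        control=cfg.control_group)
    de_tables: dict[str, DETable] = {}
    filtered_tables: dict[str, CountTable] = {}
    for level in cfg.levels:
        filtered = stage_filter(tables[level], outdir / "filter",
                                cfg.min_cpm, cfg.min_fraction)
        filtered_tables[level] = filtered
        de_tables[level] = stage_de(filtered, design, outdir / "de", cfg.de)
    plots = stage_plot(de_tables, filtered_tables[cfg.levels[0]], design,
                       outdir / "plots", cfg.de.fc_threshold, cfg.de.alpha,
                       cfg.top_k)
    return {"bundle": bundle, "counts": tables, "filtered": filtered_tables,
            "de": de_tables, "plots": plots}
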