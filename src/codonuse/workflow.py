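"""End-to-end multispecies pipeline and its on-disk report bundle.

Stages run in a fixed order — filtering, GC content, neutrality and
ENc-plot diagnostics, high-frequency codons, codon pairs, comparison
and clustering, dinucleotide statistics — and every tabular output is
TSV with a comment header carrying the package version, a config hash
and the seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cluster import build_rscu_matrix, gc_gc3_distribution, hierarchical_cluster
from .dinuc import correlation_matrix, signature_frame, species_profile
from .encplot import deviation_histogram, enc_plot_table, neutrality_regression
from .ingest import (
    filter_collection,
    filter_report_frame,
    read_cds_fasta,
    write_fasta,
)
from .metrics import (
    count_codons,
    gene_metrics,
    high_frequency_codons,
    rscu,
    species_summary,
    summary_frame,
)
from .pairs import count_codon_pairs, high_frequency_pairs, rscpu, rscpu_frame

#: Files every successful run writes (plus per-species filtered FASTA).
ARTIFACTS: tuple[str, ...] = (
    "filter_report.tsv",
    "species_summary.tsv",
    "gene_metrics.tsv",
    "neutrality_regression.tsv",
    "enc_plot_points.tsv",
    "enc_deviation_histogram.tsv",
    "high_frequency_codons.tsv",
    "rscpu.tsv",
    "high_frequency_pairs.tsv",
    "dinuc_signatures.tsv",
    "correlation_matrix.tsv",
    "rscu_matrix.tsv",
    "gc_gc3_distribution.tsv",
    "dendrogram_species.nwk",
    "dendrogram_codons.nwk",
)


@dataclass
class WorkflowConfig:
    """Everything a full run needs, in one reproducible record."""

    manifest: dict[str, str]  # species label -> CDS FASTA path
    rscu_threshold: float = 1.5
    share_threshold: float = 0.60
    gc_aggregation: str = "pooled"  # or "gene_mean"
    neutrality_x: str = "gc3"  # or "gc3s"
    hist_bin_width: float = 0.05
    metric: str = "euclidean"
    linkage: str = "average"
    min_length: int = 0
    seed: int = 0
    out_dir: str = "codonuse_out"
    write_filtered_fasta: bool = True
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.manifest:
            raise ValueError("manifest must name at least one species")
        if self.rscu_threshold <= 0 or self.share_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.neutrality_x not in ("gc3", "gc3s"):
            raise ValueError(f"unknown neutrality_x {self.neutrality_x!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kwargs = {k: v for k, v in data.items() if k in known}
        kwargs["extras"] = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs)

    def hash(self) -> str:
        payload = json.dumps(
            {
                k: getattr(self, k)
                for k in sorted(self.__dataclass_fields__)
                if k != "extras"
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


class WorkflowError(RuntimeError):
    """A stage failure, tagged with the stage and species involved."""

    def __init__(self, stage: str, species: str | None, cause: Exception):
        self.stage = stage
        self.species = species
        where = f"stage {stage!r}" + (f", species {species!r}" if species else "")
        super().__init__(f"workflow aborted at {where}: {cause}")


def _header(config: WorkflowConfig) -> str:
    return (
        f"# codonuse {__version__}\n"
        f"# config_hash={config.hash()}\n"
        f"# seed={config.seed}\n"
    )


def _write_tsv(
    df: pd.DataFrame, path: Path, config: WorkflowConfig, index: bool = False,
    index_label: str | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=index, index_label=index_label,
                  lineterminator="\n")


def run_workflow(config: WorkflowConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle.

    Returns artifact name -> path.  Any stage failure removes the
    partial outputs and raises :class:`WorkflowError` naming the stage
    and species.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out_dir, written)
    except WorkflowError:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    except Exception as exc:  # pragma: no cover - defensive
        for path in written:
            path.unlink(missing_ok=True)
        raise WorkflowError("unknown", None, exc) from exc


def _run(
    config: WorkflowConfig, out_dir: Path, written: list[Path]
) -> dict[str, Path]:
    paths: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, **kw) -> None:
        path = out_dir / name
        _write_tsv(df, path, config, **kw)
        written.append(path)
        paths[name] = path

    # -- data preprocessing ------------------------------------------------
    collections = {}
    reports = []
    for species, fasta in config.manifest.items():
        try:
            raw = read_cds_fasta(fasta, species)
            coll, report = filter_collection(
                raw, species, min_length=config.min_length
            )
        except Exception as exc:
            raise WorkflowError("preprocessing", species, exc) from exc
        if coll.n_genes == 0:
            raise WorkflowError(
                "preprocessing", species,
                ValueError("no sequences survived filtering"),
            )
        collections[species] = coll
        reports.append(report)
        if config.write_filtered_fasta:
            fdir = out_dir / "filtered"
            fdir.mkdir(exist_ok=True)
            fpath = fdir / f"{species}.fasta"
            write_fasta(coll, fpath)
            written.append(fpath)
    emit("filter_report.tsv", filter_report_frame(reports))

    # -- GC content analysis ----------------------------------------------
    try:
        summaries = [
            species_summary(c, gc_aggregation=config.gc_aggregation)
            for c in collections.values()
        ]
        emit("species_summary.tsv", summary_frame(summaries))
        metrics_by_species = {
            sp: [gene_metrics(rec) for rec in coll]
            for sp, coll in collections.items()
        }
        gene_rows = [
            {
                "species": sp,
                "gene_id": m.gene_id,
                "gc": m.gc,
                "gc1": m.gc1,
                "gc2": m.gc2,
                "gc3": m.gc3,
                "gc12": m.gc12,
                "gc3s": m.gc3s,
                "enc": m.enc,
            }
            for sp, ms in metrics_by_species.items()
            for m in ms
        ]
        emit("gene_metrics.tsv", pd.DataFrame(gene_rows))
    except WorkflowError:
        raise
    except Exception as exc:
        raise WorkflowError("gc_content", None, exc) from exc

    # -- neutrality plot and ENc plot -------------------------------------
    try:
        reg_rows, point_rows, hist_rows = [], [], []
        for sp, ms in metrics_by_species.items():
            if config.neutrality_x == "gc3":
                xs = [m.gc3 for m in ms]
                ys = [m.gc12 for m in ms]
            else:
                xs = [m.gc3s for m in ms if m.gc3s is not None]
                ys = [m.gc12 for m in ms if m.gc3s is not None]
            fit = neutrality_regression(ys, xs)
            reg_rows.append(
                {
                    "species": sp,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r2": fit.r2,
                    "p_value": fit.p_value,
                    "n_genes": fit.n_genes,
                }
            )
            points, n_omitted = enc_plot_table(ms)
            for p in points:
                point_rows.append(
                    {
                        "species": sp,
                        "gene_id": p.gene_id,
                        "gc3s_fraction": p.gc3s_fraction,
                        "enc_obs": p.enc_obs,
                        "enc_exp": p.enc_exp,
                        "deviation": p.deviation,
                    }
                )
            hist = deviation_histogram(points, bin_width=config.hist_bin_width)
            for k in range(len(hist.fractions)):
                hist_rows.append(
                    {
                        "species": sp,
                        "bin_left": hist.edges[k],
                        "bin_right": hist.edges[k + 1],
                        "fraction": hist.fractions[k],
                    }
                )
            hist_rows.append(
                {
                    "species": sp,
                    "bin_left": 0.0,
                    "bin_right": 0.1,
                    "fraction": hist.fraction_in_0_01,
                }
            )
        emit("neutrality_regression.tsv", pd.DataFrame(reg_rows))
        emit("enc_plot_points.tsv", pd.DataFrame(point_rows))
        emit("enc_deviation_histogram.tsv", pd.DataFrame(hist_rows))
    except WorkflowError:
        raise
    except Exception as exc:
        raise WorkflowError("enc_plot", None, exc) from exc

    # -- high-frequency codons --------------------------------------------
    try:
        rscu_tables = {
            sp: rscu(count_codons(coll)) for sp, coll in collections.items()
        }
        hf_rows = []
        for sp, table in rscu_tables.items():
            hf = high_frequency_codons(
                table,
                rscu_threshold=config.rscu_threshold,
                share_threshold=config.share_threshold,
            )
            for codon, val, share in hf.entries:
                hf_rows.append(
                    {
                        "species": sp,
                        "codon": codon,
                        "rscu": val,
                        "share": share,
                        "n_total": hf.n,
                    }
                )
        emit("high_frequency_codons.tsv", pd.DataFrame(hf_rows))
    except Exception as exc:
        raise WorkflowError("high_frequency_codons", None, exc) from exc

    # -- codon pairs --------------------------------------------------------
    try:
        pair_frames = []
        pair_summary = []
        for sp, coll in collections.items():
            table = rscpu(count_codon_pairs(coll))
            frame = rscpu_frame(
                table,
                rscpu_threshold=config.rscu_threshold,
                share_threshold=config.share_threshold,
            )
            frame.insert(0, "species", sp)
            pair_frames.append(frame)
            flagged = high_frequency_pairs(
                table,
                rscpu_threshold=config.rscu_threshold,
                share_threshold=config.share_threshold,
            )
            pair_summary.append(
                {"species": sp, "n_high_frequency_pairs": len(flagged)}
            )
        emit("rscpu.tsv", pd.concat(pair_frames, ignore_index=True))
        emit("high_frequency_pairs.tsv", pd.DataFrame(pair_summary))
    except Exception as exc:
        raise WorkflowError("codon_pairs", None, exc) from exc

    # -- comparison and cluster analysis -----------------------------------
    try:
        matrix, _ = build_rscu_matrix(rscu_tables)
        emit("rscu_matrix.tsv", matrix, index=True, index_label="species")
        emit("gc_gc3_distribution.tsv", gc_gc3_distribution(summaries))
        if len(collections) >= 2:
            dendros = hierarchical_cluster(
                matrix,
                metric=config.metric,
                linkage=config.linkage,
                axis="both",
            )
            for axis, name in (
                ("rows", "dendrogram_species.nwk"),
                ("columns", "dendrogram_codons.nwk"),
            ):
                path = out_dir / name
                with open(path, "w") as fh:
                    fh.write(_header(config))
                    fh.write(dendros[axis].to_newick() + "\n")
                written.append(path)
                paths[name] = path
    except Exception as exc:
        raise WorkflowError("cluster", None, exc) from exc

    # -- statistical analysis (dinucleotide signatures) ---------------------
    try:
        profiles = [species_profile(coll) for coll in collections.values()]
        emit(
            "dinuc_signatures.tsv",
            signature_frame(profiles),
            index=True,
            index_label="species",
        )
        if len(profiles) >= 2:
            emit(
                "correlation_matrix.tsv",
                correlation_matrix(profiles),
                index=True,
                index_label="species",
            )
    except Exception as exc:
        raise WorkflowError("statistics", None, exc) from exc

    return paths
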