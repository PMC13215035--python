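"""End-to-end orchestration: cohort in, SE calls, consensus, TF screen out.

``run_screen`` drives the whole analysis from a TOML config (or an
in-memory dict with the same sections): optional simulation, per-sample SE
calling, consensus construction with the presence filter, prioritization,
gene assignment, the TF screen, optional downstream annotation, plot-data
export, and a JSON run manifest with SHA-256 hashes of every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from . import __version__
from .annotation import (
    DEFAULT_PROMOTER_WINDOW,
    classify_gene_peaks,
    overlap_gene_sets,
    summarize_peak_fractions,
)
from .calling import SampleSECalls, StitchParams, call_sample
from .consensus import (
    ConsensusSE,
    ScreenConfig,
    aggregate_and_prioritize,
    assign_genes,
    build_consensus,
    filter_presence,
    screen_tfs,
)
from .intervals import GenomicInterval
from .io import (
    read_bed,
    read_bedgraph,
    read_de_table,
    read_disease_lists,
    read_gene_annotation,
    write_bed,
)
from .simulate import PlantedSE, SimConfig, simulate_cohort

__all__ = ["PipelineError", "RunResult", "load_config", "run_screen", "write_sample_outputs"]

logger = logging.getLogger("sescreen")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunResult:
    outdir: Path
    calls: list[SampleSECalls]
    consensus: list[ConsensusSE]
    tf_table: pd.DataFrame
    summary: dict[str, Any]
    manifest_path: Path


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a TOML config with [cohort]/[se_calling]/[consensus]/
    [annotation]/[simulate] sections (all optional except one of
    [cohort]/[simulate])."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sim_config_from_dict(sim: dict[str, Any], seed: int | None) -> SimConfig:
    kwargs: dict[str, Any] = {}
    for key in (
        "n_samples", "n_genes", "tf_fraction", "n_background_peaks",
        "background_shape", "background_scale", "noise_sd", "stitch_distance",
    ):
        if key in sim:
            kwargs[key] = sim[key]
    if "seed" in sim:
        kwargs["seed"] = sim["seed"]
    if seed is not None:
        kwargs["seed"] = seed
    if "genome" in sim:
        kwargs["genome"] = tuple((str(c), int(n)) for c, n in sim["genome"])
    if "peak_width" in sim:
        kwargs["peak_width"] = tuple(sim["peak_width"])
    if "planted_ses" in sim:
        kwargs["planted_ses"] = tuple(
            PlantedSE(**{**p, "present_in": tuple(p["present_in"])})
            for p in sim["planted_ses"]
        )
    return SimConfig(**kwargs)


def write_sample_outputs(calls: SampleSECalls, outdir: Path) -> list[Path]:
    """Write one sample's stitched/SE/TE BEDs, rank table and hockey-plot TSV."""
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    regions = calls.regions  # rank order, strongest first

    def bed(path: Path, subset) -> None:
        rows = sorted(subset, key=lambda r: r.interval.sort_key())
        write_bed(
            [
                GenomicInterval(
                    r.interval.chrom, r.interval.start, r.interval.end,
                    name=("SE" if r.is_super else "TE") + f"_rank{r.rank}",
                )
                for r in rows
            ],
            path,
            scores=[r.signal for r in rows],
        )
        paths.append(path)

    bed(outdir / f"{calls.sample_id}_stitched.bed", regions)
    bed(outdir / f"{calls.sample_id}_SE.bed", calls.super_enhancers())
    bed(outdir / f"{calls.sample_id}_TE.bed", calls.typical_enhancers())

    rank_path = outdir / f"{calls.sample_id}_ranktable.tsv"
    with open(rank_path, "w") as fh:
        fh.write("region\tn_constituents\tsignal\trank\tis_super\n")
        for r in regions:
            fh.write(
                f"{r.interval.chrom}:{r.interval.start}-{r.interval.end}\t"
                f"{r.n_constituents}\t{r.signal:.6g}\t{r.rank}\t{int(r.is_super)}\n"
            )
    paths.append(rank_path)

    # hockey-stick data: ascending signal order, axes scaled to [0, 1]
    hockey_path = outdir / f"{calls.sample_id}_hockey.tsv"
    n = len(regions)
    max_signal = max(r.signal for r in regions) or 1.0
    ascending = sorted(regions, key=lambda r: -r.rank)
    with open(hockey_path, "w") as fh:
        fh.write("scaled_rank\tscaled_signal\tis_super\tis_cutoff\n")
        for i, r in enumerate(ascending, start=1):
            fh.write(
                f"{i / n:.6g}\t{r.signal / max_signal:.6g}\t{int(r.is_super)}\t"
                f"{int(i == calls.cutoff_index)}\n"
            )
    paths.append(hockey_path)
    return paths


def write_consensus_outputs(
    consensus: Sequence[ConsensusSE], outdir: Path
) -> list[Path]:
    """consensus_SE.bed, consensus_SE.tsv and the rank/intensity scatter."""
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    ordered = sorted(consensus, key=lambda c: c.priority)

    bed_path = outdir / "consensus_SE.bed"
    rows = sorted(ordered, key=lambda c: c.interval.sort_key())
    write_bed(
        [
            GenomicInterval(c.interval.chrom, c.interval.start, c.interval.end,
                            name=f"consensusSE_{c.priority}")
            for c in rows
        ],
        bed_path,
        scores=[c.avg_intensity for c in rows],
    )
    paths.append(bed_path)

    tsv_path = outdir / "consensus_SE.tsv"
    with open(tsv_path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tpresence\tavg_rank\tavg_intensity\tpriority\t"
            "is_tf_se\tgenes\n"
        )
        for c in ordered:
            gene_str = ",".join(f"{g.gene_id}({g.distance})" for g in c.genes) or "."
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                f"{c.presence}\t{c.avg_rank:.6g}\t{c.avg_intensity:.6g}\t"
                f"{c.priority}\t{int(c.is_tf_se)}\t{gene_str}\n"
            )
    paths.append(tsv_path)

    scatter_path = outdir / "rank_intensity_points.tsv"
    with open(scatter_path, "w") as fh:
        fh.write("avg_rank\tavg_intensity\tis_tf_se\tlabel\n")
        for c in ordered:
            tf_genes = ",".join(g.gene_id for g in c.genes if g.is_tf) or "."
            fh.write(
                f"{c.avg_rank:.6g}\t{c.avg_intensity:.6g}\t{int(c.is_tf_se)}\t{tf_genes}\n"
            )
    paths.append(scatter_path)
    return paths


def run_screen(
    config: dict[str, Any] | str | Path,
    outdir: str | Path,
    seed: int | None = None,
    min_presence: int | None = None,
    stitch_distance: int | None = None,
    tss_window: int | None = None,
) -> RunResult:
    """Run the full screen per the config; returns results and writes files.

    Explicit keyword overrides take precedence over the config file.  The
    config needs either a [simulate] section (synthetic cohort) or a
    [cohort] section naming per-sample peak/signal files, the gene
    annotation and the TF list.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    summary: dict[str, Any] = {}

    # ---- stage: cohort (simulate or load) ----------------------------------
    cohort = dict(config.get("cohort", {}))
    if "simulate" in config:
        sim_config = _sim_config_from_dict(dict(config["simulate"]), seed)
        files = simulate_cohort(sim_config, outdir / "cohort")
        cohort = {
            "samples": [
                {
                    "id": s,
                    "peaks": str(files.peak_beds[s]),
                    "signal": str(files.signal_bedgraphs[s]),
                }
                for s in files.sample_ids
            ],
            "genes": str(files.genes_tsv),
            "tf_list": str(files.tf_list),
        }
        outputs += [files.genes_tsv, files.tf_list, files.truth_tsv]
        outputs += list(files.peak_beds.values()) + list(files.signal_bedgraphs.values())
        summary["simulated"] = True
        summary["seed"] = sim_config.seed
    if not cohort.get("samples"):
        raise PipelineError("config error: no samples (need [simulate] or [cohort].samples)")
    for s in cohort["samples"]:
        for key in ("id", "peaks", "signal"):
            if key not in s:
                raise PipelineError(f"config error: sample entry missing {key!r}: {s}")
        for key in ("peaks", "signal"):
            if not Path(s[key]).exists():
                raise PipelineError(
                    f"sample {s['id']}: missing {key} file {s[key]}"
                )
    if "genes" not in cohort or "tf_list" not in cohort:
        raise PipelineError("config error: [cohort] needs genes and tf_list")

    genes = read_gene_annotation(cohort["genes"], cohort["tf_list"])

    # ---- stage: per-sample SE calling --------------------------------------
    se_cfg = dict(config.get("se_calling", {}))
    if stitch_distance is not None:
        se_cfg["stitch_distance"] = stitch_distance
    if tss_window is not None:
        se_cfg["tss_exclusion_window"] = tss_window
    params = StitchParams(
        stitch_distance=int(se_cfg.get("stitch_distance", 12500)),
        tss_exclusion_window=int(se_cfg.get("tss_exclusion_window", 2500)),
        quantify_mode=str(se_cfg.get("quantify_mode", "constituents")),
        clamp_negative=bool(se_cfg.get("clamp_negative", True)),
    )
    calls: list[SampleSECalls] = []
    per_sample_dir = outdir / "samples"
    sample_summaries = []
    for s in cohort["samples"]:
        try:
            peaks = read_bed(s["peaks"])
            chip = read_bedgraph(s["signal"])
            control = read_bedgraph(s["control"]) if s.get("control") else None
            sample_calls = call_sample(s["id"], peaks, chip, control, genes, params)
        except Exception as exc:
            raise PipelineError(f"SE calling failed for sample {s['id']}: {exc}") from exc
        calls.append(sample_calls)
        outputs += write_sample_outputs(sample_calls, per_sample_dir)
        sample_summaries.append(
            {
                "sample_id": s["id"],
                "peaks_in": len(peaks),
                "regions": len(sample_calls.regions),
                "n_se": sample_calls.n_se,
                "cutoff_value": sample_calls.cutoff_value,
            }
        )
    summary["samples"] = sample_summaries

    # ---- stage: consensus + screen -----------------------------------------
    cons_cfg = dict(config.get("consensus", {}))
    if min_presence is not None:
        cons_cfg["min_presence"] = min_presence
    screen_config = ScreenConfig(
        min_presence=int(cons_cfg.get("min_presence", 6)),
        gene_window=int(cons_cfg.get("gene_window", 50_000)),
        min_overlap_frac=float(cons_cfg.get("min_overlap_frac", 0.0)),
    )
    try:
        clusters = build_consensus(calls, screen_config.min_overlap_frac)
        kept = filter_presence(clusters, screen_config)
        prioritized = aggregate_and_prioritize(kept)
        for c in prioritized:
            assign_genes(c, genes, screen_config.gene_window)
        tf_table = screen_tfs(prioritized, genes)
    except Exception as exc:
        raise PipelineError(f"consensus/screen stage failed: {exc}") from exc
    outputs += write_consensus_outputs(prioritized, outdir)
    tf_path = outdir / "se_tf_screen.tsv"
    tf_table.to_csv(tf_path, sep="\t", index=False)
    outputs.append(tf_path)
    summary["consensus"] = {
        "clusters_total": len(clusters),
        "clusters_kept": len(prioritized),
        "min_presence": screen_config.min_presence,
        "n_se_total": sum(c.n_se for c in calls),
        "n_tf_hits": int(len(tf_table)),
    }

    # ---- stage: downstream annotation (optional) ---------------------------
    ann_cfg = dict(config.get("annotation", {}))
    if ann_cfg.get("de_table") and ann_cfg.get("chip_peaks"):
        try:
            de_rows = read_de_table(ann_cfg["de_table"])
            chip_peaks = read_bed(ann_cfg["chip_peaks"])
            window = tuple(ann_cfg.get("promoter_window", DEFAULT_PROMOTER_WINDOW))
            annotations = {
                g.gene_id: classify_gene_peaks(g, chip_peaks, window) for g in genes
            }
            fractions = summarize_peak_fractions(de_rows, annotations)
            frac_path = outdir / "peak_fractions.tsv"
            with open(frac_path, "w") as fh:
                fh.write(f"# promoter_window={window[0]},{window[1]}\n")
                fractions.to_csv(fh, sep="\t", index=False)
            outputs.append(frac_path)
            summary["peak_fractions"] = fractions.to_dict(orient="records")
            if ann_cfg.get("disease_lists"):
                lists = read_disease_lists(ann_cfg["disease_lists"])
                records, counts, union = overlap_gene_sets(de_rows, lists)
                overlap_path = outdir / "gwas_overlap.tsv"
                records.to_csv(overlap_path, sep="\t", index=False)
                outputs.append(overlap_path)
                summary["disease_overlap"] = {
                    "per_list": counts,
                    "union_de_genes": union,
                }
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"annotation stage failed: {exc}") from exc

    # ---- summary + manifest -------------------------------------------------
    summary_path = outdir / "summary.txt"
    with open(summary_path, "w") as fh:
        fh.write(f"sescreen v{__version__}\n")
        fh.write(f"samples: {len(calls)}\n")
        for s in sample_summaries:
            fh.write(
                f"  {s['sample_id']}: peaks_in={s['peaks_in']} regions={s['regions']} "
                f"n_se={s['n_se']} cutoff={s['cutoff_value']:.6g}\n"
            )
        cs = summary["consensus"]
        fh.write(
            f"consensus: clusters={cs['clusters_total']} kept={cs['clusters_kept']} "
            f"(min_presence={cs['min_presence']}) tf_hits={cs['n_tf_hits']}\n"
        )

    manifest = {
        "tool": "sescreen",
        "version": __version__,
        "generated_at": datetime.now(timezone.utc).isoformat(),
        "seed": summary.get("seed"),
        "config": _jsonable(config),
        "parameters": {
            "stitch_distance": params.stitch_distance,
            "tss_exclusion_window": params.tss_exclusion_window,
            "quantify_mode": params.quantify_mode,
            "clamp_negative": params.clamp_negative,
            "min_presence": screen_config.min_presence,
            "gene_window": screen_config.gene_window,
            "min_overlap_frac": screen_config.min_overlap_frac,
        },
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(outputs))
        },
        "summary": _jsonable(summary),
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return RunResult(
        outdir=outdir,
        calls=calls,
        consensus=prioritized,
        tf_table=tf_table,
        summary=summary,
        manifest_path=manifest_path,
    )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
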