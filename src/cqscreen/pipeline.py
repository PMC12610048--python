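"""End-to-end orchestration: simulate -> count -> screen -> merge -> flanks -> pcr.

``run_all`` executes the whole discovery workflow on a synthetic genome,
writes every intermediate artifact in its standard format (FASTA, SAM, BED,
TSV), evaluates the reported regions against the planted truth intervals,
and records everything needed to reproduce the run in a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .cq import ScreenConfig
from .model import ChromosomeQuotientScreen, ScreenResults
from .pcr import MarkerCall, PrimerPair, classify_marker, genotype_bands
from .regions import Region, extract_flanks, regions_to_bed, regions_to_tsv
from .simulate import (
    ReadSimParams,
    SexGenome,
    SexGenomeSpec,
    build_genome,
    simulate_pool,
    write_reference_fasta,
    write_sam,
    write_truth_bed,
)
from .windows import CountFilters, counts_to_tsv
from .cq import records_to_tsv

logger = logging.getLogger("cqscreen")

__all__ = ["PipelineError", "RunManifest", "run_all", "load_run_config", "run_from_config", "evaluate_regions"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    """Everything needed to reproduce a run, plus per-stage bookkeeping."""

    config: dict
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    sensitivity: float | None = None
    precision: float | None = None
    marker_calls: dict[str, str] = field(default_factory=dict)
    version: str = __version__

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def evaluate_regions(
    reported: Sequence[Region], truth: Sequence[tuple[str, int, int]]
) -> tuple[float, float]:
    """Sensitivity (truth intervals overlapped by >= 1 reported region) and
    precision (reported regions overlapping >= 1 truth interval).

    An empty truth set gives sensitivity 1; no reported regions give
    precision 1 (nothing reported, nothing wrong)."""

    def overlaps(a: tuple[str, int, int], b: tuple[str, int, int]) -> bool:
        return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]

    rep = [(r.contig, r.start, r.end) for r in reported]
    sens = (
        sum(any(overlaps(t, r) for r in rep) for t in truth) / len(truth) if truth else 1.0
    )
    prec = (
        sum(any(overlaps(r, t) for t in truth) for r in rep) / len(rep) if rep else 1.0
    )
    return sens, prec


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


def run_all(
    genome_spec: SexGenomeSpec,
    male_params: ReadSimParams,
    female_params: ReadSimParams,
    screen_config: ScreenConfig,
    outdir: str | Path,
    primers: Sequence[PrimerPair] = (),
    flank: int = 1000,
    filters: CountFilters | None = None,
) -> RunManifest:
    """Run the full discovery workflow into ``outdir`` and return a manifest.

    Stages: build the synthetic genome, simulate both sex pools, window and
    count, screen with the chromosome quotient, merge retained windows into
    regions, extract flanks, and (if primers are supplied) predict per-sex
    band patterns for each primer pair against the X and Y-inclusive
    haplotypes around each region.  Reported regions are scored against the
    planted truth intervals.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={
            "genome": dataclasses.asdict(genome_spec),
            "male": dataclasses.asdict(male_params),
            "female": dataclasses.asdict(female_params),
            "screen": dataclasses.asdict(screen_config),
            "flank": flank,
        },
        seed=male_params.seed,
    )

    @_stage("simulate")
    def _simulate() -> SexGenome:
        genome = build_genome(genome_spec)
        write_reference_fasta(genome, outdir / "reference.fasta")
        write_truth_bed(genome, outdir / "truth.bed")
        for sex, params in (("male", male_params), ("female", female_params)):
            reads = simulate_pool(genome, sex, params)
            n = write_sam(reads, genome, outdir / f"{sex}.sam", sample=sex)
            manifest.stage_counts[f"reads_{sex}"] = n
        return genome

    genome = _simulate()
    manifest.outputs.update(
        reference=str(outdir / "reference.fasta"),
        truth=str(outdir / "truth.bed"),
        male=str(outdir / "male.sam"),
        female=str(outdir / "female.sam"),
    )

    @_stage("screen")
    def _screen() -> ScreenResults:
        model = ChromosomeQuotientScreen.from_alignments(
            outdir / "male.sam",
            outdir / "female.sam",
            config=screen_config,
            filters=filters,
            contig_lengths=genome.contig_lengths,
        )
        counts_to_tsv(model.male_counts, outdir / "counts_male.tsv")
        counts_to_tsv(model.female_counts, outdir / "counts_female.tsv")
        res = model.fit()
        records_to_tsv(res.records, outdir / "screen.tsv")
        manifest.stage_counts["windows"] = len(res.records)
        manifest.stage_counts["retained_windows"] = len(res.retained)
        return res

    results = _screen()
    manifest.outputs.update(
        counts_male=str(outdir / "counts_male.tsv"),
        counts_female=str(outdir / "counts_female.tsv"),
        screen=str(outdir / "screen.tsv"),
    )

    @_stage("regions")
    def _regions() -> None:
        regions_to_bed(results.regions, outdir / "regions.bed")
        regions_to_tsv(results.regions, outdir / "regions.tsv")
        manifest.stage_counts["regions"] = len(results.regions)

    _regions()
    manifest.outputs.update(
        regions_bed=str(outdir / "regions.bed"), regions_tsv=str(outdir / "regions.tsv")
    )

    @_stage("flanks")
    def _flanks() -> None:
        from Bio import SeqIO

        recs = [extract_flanks(r, genome.reference, flank) for r in results.regions]
        SeqIO.write(recs, str(outdir / "flanks.fasta"), "fasta")
        manifest.stage_counts["flank_records"] = len(recs)

    _flanks()
    manifest.outputs["flanks"] = str(outdir / "flanks.fasta")

    if primers:

        @_stage("pcr")
        def _pcr() -> None:
            rows = []
            for region in results.regions:
                s = max(0, region.start - flank)
                e = min(len(genome.reference[region.contig]), region.end + flank)
                y_template = genome.reference[region.contig][s:e]
                x_template = genome.x_slice(region.contig, s, e)
                for pair in primers:
                    male_pat = genotype_bands([x_template, y_template], pair)
                    female_pat = genotype_bands([x_template, x_template], pair)
                    call = classify_marker(male_pat, female_pat)
                    rows.append(
                        {
                            "region": f"{region.contig}:{region.start + 1}-{region.end}",
                            "primer": pair.name,
                            "male_bands": ",".join(map(str, male_pat.bands)),
                            "female_bands": ",".join(map(str, female_pat.bands)),
                            "call": call.value,
                        }
                    )
                    if call is MarkerCall.MALE_EXTRA_BAND:
                        manifest.marker_calls[pair.name] = call.value
            import pandas as pd

            pd.DataFrame(rows).to_csv(outdir / "markers.tsv", sep="\t", index=False)

        _pcr()
        manifest.outputs["markers"] = str(outdir / "markers.tsv")

    sens, prec = evaluate_regions(results.regions, genome.truth_regions)
    manifest.sensitivity = sens
    manifest.precision = prec
    manifest.to_json(outdir / "manifest.json")
    manifest.outputs["manifest"] = str(outdir / "manifest.json")
    logger.info(
        "done: %d regions, sensitivity %.3f, precision %.3f",
        len(results.regions),
        sens,
        prec,
    )
    return manifest


# -- plain-text run configuration ------------------------------------------


def load_run_config(path: str | Path, seed: int | None = None) -> dict[str, Any]:
    """Load a key-value run config (YAML) and normalize it into the pieces
    ``run_all`` needs.  ``seed`` overrides the file's seed when given."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if seed is not None:
        raw["seed"] = seed
    raw.setdefault("seed", 0)
    genome = SexGenomeSpec(
        contigs=tuple((c[0], int(c[1])) for c in raw["contigs"]),
        insertions=tuple((i[0], int(i[1]), int(i[2])) for i in raw.get("insertions", [])),
        base_seed=int(raw["seed"]),
        gc_fraction=float(raw.get("gc_fraction", 0.39)),
    )
    male = ReadSimParams(
        depth=float(raw.get("male_depth", 24.0)),
        read_length=int(raw.get("read_length", 150)),
        error_rate=float(raw.get("error_rate", 0.002)),
        seed=int(raw["seed"]),
    )
    female = dataclasses.replace(male, depth=float(raw.get("female_depth", 31.0)))
    screen = ScreenConfig(
        window=int(raw.get("window", 500)),
        step=int(raw.get("step", 1000)),
        cq_max=float(raw.get("cq_max", 0.2)),
        hm_min=int(raw.get("hm_min", 30)),
        normalize_depth=bool(raw.get("normalize_depth", False)),
        merge_gap=int(raw.get("merge_gap", 0)),
    )
    return {
        "genome_spec": genome,
        "male_params": male,
        "female_params": female,
        "screen_config": screen,
        "flank": int(raw.get("flank", 1000)),
    }


def run_from_config(
    path: str | Path,
    outdir: str | Path,
    seed: int | None = None,
    primers: Sequence[PrimerPair] = (),
) -> RunManifest:
    kwargs = load_run_config(path, seed=seed)
    return run_all(outdir=outdir, primers=primers, **kwargs)
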