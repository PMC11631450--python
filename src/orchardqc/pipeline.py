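"""Pipeline driver: wire the QC stages together with a self-describing report.

Stages run in the fixed order
``curate -> evidence -> subset -> rename -> orthostats -> haplobin -> stats``
(any subset may be enabled).  Every stage records its parameters and the
SHA-256 digest of each file it writes into ``report.json``, so two runs
with identical configuration and inputs produce identical report digests.
A stage failure aborts the run, names the failing stage, and leaves a
``FAILED.<stage>`` marker next to the partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import curation, evidence, haplobin, nomenclature, orthostats, seqstats
from .annotation_io import (
    RepeatTrack,
    UsageError,
    read_gff3,
    read_repeat_bed,
    write_gff3,
)

logger = logging.getLogger("orchardqc")

STAGE_ORDER = ("curate", "evidence", "subset", "rename", "orthostats",
               "haplobin", "stats")


@dataclass
class PipelineConfig:
    outdir: Path
    stages: list[str] = field(default_factory=list)
    params: dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        stages = list(raw.get("stages", []))
        unknown = [s for s in stages if s not in STAGE_ORDER]
        if unknown:
            raise UsageError(f"unknown stage(s): {unknown}")
        return cls(
            outdir=Path(raw.get("outdir", "orchardqc_out")),
            stages=stages,
            params={s: dict(raw.get(s, {}) or {}) for s in STAGE_ORDER},
            seed=int(raw.get("seed", 0)),
        )

    def validate_inputs(self) -> None:
        """Fail before any stage runs if a referenced input path is missing."""
        for stage in self.stages:
            for key, value in self.params.get(stage, {}).items():
                if key in ("gff", "repeats", "rna", "protein", "functional",
                           "orthogroup_ids", "fasta", "scaffolds", "parent_a",
                           "parent_b", "paf"):
                    if value and not Path(value).exists():
                        raise UsageError(
                            f"stage {stage}: input {key}={value} does not exist"
                        )
                if key == "assignments":
                    for p in value or []:
                        if not Path(p).exists():
                            raise UsageError(
                                f"stage {stage}: assignment table {p} missing"
                            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageFailure(UsageError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the report bundle."""
    config.validate_inputs()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": []}
    state: dict = {}

    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        params = config.params.get(stage, {})
        entry = {"stage": stage, "params": {k: str(v) for k, v in params.items()},
                 "outputs": {}}
        try:
            outputs = _STAGE_FUNCS[stage](params, state, out)
        except Exception as exc:
            (out / f"FAILED.{stage}").write_text(str(exc) + "\n")
            report["stages"].append(entry | {"error": str(exc)})
            (out / "report.json").write_text(json.dumps(report, indent=2))
            raise StageFailure(stage, exc) from exc
        for path in outputs:
            entry["outputs"][path.name] = _sha256(path)
        report["stages"].append(entry)
        logger.info("stage %s done (%d outputs)", stage, len(outputs))

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


# --- stage implementations -------------------------------------------------


def _stage_curate(params: dict, state: dict, out: Path) -> list[Path]:
    annotation = read_gff3(params["gff"])
    repeats = (read_repeat_bed(params["repeats"])
               if params.get("repeats") else RepeatTrack())
    cfg = curation.CurationConfig(
        repeat_fraction_threshold=float(params.get("threshold", 0.90))
    )
    curated, rep = curation.curate(annotation, repeats, cfg)
    gff_out = out / "curated.gff3"
    report_out = out / "curation_report.tsv"
    write_gff3(curated, gff_out)
    curation.write_report_tsv(rep, report_out)
    state["annotation"] = curated
    return [gff_out, report_out]


def _get_annotation(params: dict, state: dict):
    if "annotation" in state:
        return state["annotation"]
    if "gff" not in params:
        raise UsageError("no curated annotation in pipeline state and no 'gff' given")
    return read_gff3(params["gff"])


def _stage_evidence(params: dict, state: dict, out: Path) -> list[Path]:
    annotation = _get_annotation(params, state)
    cov = evidence.EvidenceCoverage.from_bed(params.get("rna"),
                                             params.get("protein"))
    functional = (set(Path(params["functional"]).read_text().split())
                  if params.get("functional") else set())
    og_ids = (set(Path(params["orthogroup_ids"]).read_text().split())
              if params.get("orthogroup_ids") else set())
    flags = evidence.compute_support_table(annotation, cov, functional, og_ids)
    flags_out = out / "flags.tsv"
    evidence.write_flags_tsv(flags, flags_out)
    state["annotation"] = annotation
    state["flags"] = flags
    return [flags_out]


def _stage_subset(params: dict, state: dict, out: Path) -> list[Path]:
    annotation = _get_annotation(params, state)
    flags = state.get("flags")
    if flags is None:
        flags = evidence.read_flags_tsv(params["flags"])
    outputs = []
    levels = params.get("levels", [1, 2, 3, 4])
    for level in levels:
        members = evidence.select_subset(annotation, flags, int(level))
        p = out / f"subset{level}.txt"
        p.write_text("\n".join(sorted(members)) + "\n")
        outputs.append(p)
    return outputs


def _stage_rename(params: dict, state: dict, out: Path) -> list[Path]:
    annotation = _get_annotation(params, state)
    chrom_map = params.get("chrom_map") or {}
    if isinstance(chrom_map, str):
        chrom_map = dict(
            line.split("\t")[:2]
            for line in Path(chrom_map).read_text().splitlines() if line.strip()
        )
    renamed, mapping = nomenclature.rename_annotation(
        annotation,
        tol_prefix=params.get("tol_prefix", "drMalDome"),
        cultivar=params.get("cultivar", "wa38"),
        version=params.get("version", "v1a1"),
        chromosome_map=chrom_map,
        unplaced_token=params.get("unplaced_token"),
    )
    gff_out = out / "renamed.gff3"
    map_out = out / "idmap.tsv"
    write_gff3(renamed, gff_out)
    map_out.write_text("\n".join(f"{o}\t{n}" for o, n in mapping) + "\n")
    state["annotation"] = renamed
    return [gff_out, map_out]


def _stage_orthostats(params: dict, state: dict, out: Path) -> list[Path]:
    assignments = [
        orthostats.OrthogroupAssignment.from_tsv(p)
        for p in params.get("assignments", [])
    ]
    mat = orthostats.build_crog_matrix(assignments)
    z, dropped = orthostats.zscore_normalize(mat)
    counts_out = out / "crog_counts.tsv"
    z_out = out / "crog_zscores.tsv"
    dropped_out = out / "crog_dropped_rows.txt"
    upset_out = out / "upset_counts.tsv"
    mat.to_csv(counts_out, sep="\t")
    z.to_csv(z_out, sep="\t")
    dropped_out.write_text("\n".join(dropped) + ("\n" if dropped else ""))
    sets = {a.genome: a.orthogroups() for a in assignments}
    orthostats.write_upset_tsv(orthostats.upset_counts(sets), upset_out)
    outputs = [counts_out, z_out, dropped_out, upset_out]
    if params.get("plots"):
        cm = out / "crog_clustermap.png"
        bx = out / "crog_zscore_boxplot.png"
        orthostats.plot_clustermap(z, cm)
        orthostats.plot_zscore_boxplot(z, bx)
        outputs += [cm, bx]
    return outputs


def _stage_haplobin(params: dict, state: dict, out: Path) -> list[Path]:
    k = int(params.get("k", 21))
    scaffolds = seqstats.read_fasta(params["scaffolds"])
    markers_a = haplobin.kmerset_from_sequences(
        seqstats.read_fasta(params["parent_a"]), k)
    markers_b = (haplobin.kmerset_from_sequences(
        seqstats.read_fasta(params["parent_b"]), k)
        if params.get("parent_b") else None)
    calls = haplobin.assign_haplomes(
        scaffolds, markers_a, markers_b,
        min_margin=float(params.get("min_margin", 0.02)),
        min_count=int(params.get("min_count", 1000)),
    )
    p = out / "haplome_calls.tsv"
    lines = ["scaffold\tscore_A\tscore_B\tmargin\tcall\tinformative_kmers"]
    for c in calls:
        lines.append(f"{c.scaffold}\t{c.score_a:.6f}\t{c.score_b:.6f}"
                     f"\t{c.margin:.6f}\t{c.call}\t{c.informative_kmers}")
    p.write_text("\n".join(lines) + "\n")
    return [p]


def _stage_stats(params: dict, state: dict, out: Path) -> list[Path]:
    sequences = seqstats.read_fasta(params["fasta"])
    st = seqstats.assembly_stats(sequences)
    p = out / "assembly_stats.tsv"
    p.write_text(
        "n_sequences\ttotal_length\tn50\tl50\tgc_fraction\n"
        f"{st.n_sequences}\t{st.total_length}\t{st.n50}\t{st.l50}"
        f"\t{st.gc_fraction:.6f}\n"
    )
    outputs = [p]
    if params.get("telomere", True):
        hits = seqstats.telomere_scan_assembly(
            sequences,
            min_unit=int(params.get("min_unit", 2)),
            max_unit=int(params.get("max_unit", 20)),
        )
        t = out / "telomeres.tsv"
        lines = ["sequence\tend\tunit\tcopies"]
        lines += [f"{h.sequence_id}\t{h.end}\t{h.unit}\t{h.copies}" for h in hits]
        t.write_text("\n".join(lines) + "\n")
        outputs.append(t)
    return outputs


_STAGE_FUNCS = {
    "curate": _stage_curate,
    "evidence": _stage_evidence,
    "subset": _stage_subset,
    "rename": _stage_rename,
    "orthostats": _stage_orthostats,
    "haplobin": _stage_haplobin,
    "stats": _stage_stats,
}
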