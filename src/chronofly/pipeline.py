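"""Config-driven simulate -> analyze -> report pipeline.

Stages run sequentially and communicate via files only, so every
intermediate is inspectable.  A run manifest records the config hash,
seed, and a checksum for every input and output, making reruns with the
same config and seed verifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from . import locomotor, motifscan, qpcr, synthetic_data
from .schedules import LightSchedule

STAGES = ("simulate", "activity", "qpcr", "motifs")

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "out_dir": "chronofly_out",
    "stages": ["simulate", "activity", "qpcr", "motifs"],
    "simulate": {
        "activity": {
            "n_flies": 16,
            "n_days": 14,
            "schedule": "LD12:12@08:00",
            "temperature": 25.0,
            "tau": 24.0,
            "baseline": 2.0,
            "dark_attenuation": 0.3,
            "arrhythmic_fraction": 0.0,
            "peaks": [{"center_zt": 10.0, "width_sd": 2.0, "height": 10.0}],
        },
        "qpcr": {
            "genes": [
                {"name": "per", "mesor": 1.0, "amplitude": 0.5, "peak_zt": 14.0,
                 "cycling": True},
            ],
            "conditions": {"25": 0.0},
            "ref_gene": "rp49",
            "tech_sd": 0.15,
            "bio_sd": 0.25,
        },
        "splice": {
            "efficiencies": {"15": 0.98, "25": 0.99, "35": 0.99},
            "noise_sd": 0.05,
            "n_reps": 3,
        },
        "promoter": {
            "length_bp": 5000,
            "gc_fraction": 0.5,
            "plants": [{"motif": "TTATGTAA", "count": 4}],
        },
    },
    "activity": {
        "day_range": [1, 10],
        "smooth_factor": 2,
        "periodogram_range": [16.0, 32.0],
        "alpha": 0.05,
    },
    "qpcr": {
        "ref_gene": "rp49",
        "efficiency": 2.0,
        "max_spread": 0.5,
        "phase_method": "argmax",
    },
    "motifs": {
        "motif_set": dict(motifscan.DEFAULT_MOTIFS),
        "background": "uniform",
    },
}


@dataclass
class RunConfig:
    seed: int
    out_dir: Path
    stages: list[str]
    params: dict[str, Any] = field(default_factory=dict)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    started: str
    finished: str
    stage_files: dict[str, dict[str, str]]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


# mappings whose keys are user data (condition labels, motif names), not schema
_FREEFORM_KEYS = {"conditions", "efficiencies", "motif_set"}


def _merge(defaults: Any, override: Any, path: str = "") -> Any:
    if override is None:
        return defaults
    if isinstance(defaults, dict):
        if not isinstance(override, dict):
            raise ValueError(f"config key {path or '<root>'}: expected a mapping")
        if path.rsplit(".", 1)[-1] in _FREEFORM_KEYS:
            return override
        unknown = set(override) - set(defaults)
        if unknown:
            raise ValueError(
                f"unknown config key(s) {sorted(unknown)} under {path or '<root>'}"
            )
        return {
            k: _merge(defaults[k], override.get(k), f"{path}.{k}".lstrip("."))
            for k in defaults
        }
    return override


def validate_config(path) -> RunConfig:
    """Load a YAML run config, fill defaults, and reject unknown keys.

    An empty file yields the defaults-only config; normalization is
    idempotent.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    merged = _merge(_DEFAULTS, raw)
    stages = merged["stages"]
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stage(s) {bad}; valid stages are {list(STAGES)}")
    return RunConfig(
        seed=int(merged["seed"]),
        out_dir=Path(merged["out_dir"]),
        stages=list(stages),
        params={k: merged[k] for k in ("simulate", "activity", "qpcr", "motifs")},
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params["simulate"]
    written = []
    act = p["activity"]
    ds = synthetic_data.simulate_activity(synthetic_data.ActivitySimConfig(
        n_flies=act["n_flies"], n_days=act["n_days"],
        schedule=LightSchedule.parse(act["schedule"]),
        period_tau=act["tau"], baseline=act["baseline"],
        dark_attenuation=act["dark_attenuation"],
        arrhythmic_fraction=act["arrhythmic_fraction"],
        temperature_label=act["temperature"],
        peaks=[synthetic_data.ActivityPeak(pk["center_zt"], pk["width_sd"],
                                           pk["height"]) for pk in act["peaks"]],
        seed=cfg.seed,
    ))
    monitor = out / "monitor.txt"
    locomotor.write_monitor_file(ds, monitor)
    written.append(monitor)

    qp = p["qpcr"]
    tables = []
    for i, (cond, shift) in enumerate(sorted(qp["conditions"].items())):
        genes = [synthetic_data.GeneSpec(
            g["name"], g["mesor"], g["amplitude"],
            (g["peak_zt"] + shift) % 24.0, g["cycling"],
        ) for g in qp["genes"]]
        tables.append(synthetic_data.simulate_qpcr(synthetic_data.QpcrSimConfig(
            genes=genes, condition_label=str(cond), ref_gene=qp["ref_gene"],
            tech_sd=qp["tech_sd"], bio_sd=qp["bio_sd"], seed=cfg.seed + 1 + i,
        )))
    cq_path = out / "cq_table.tsv"
    pd.concat(tables, ignore_index=True).to_csv(cq_path, sep="\t", index=False)
    written.append(cq_path)

    sp = p["splice"]
    splice = synthetic_data.simulate_splice_assay(
        {str(k): v for k, v in sp["efficiencies"].items()},
        noise_sd=sp["noise_sd"], n_reps=sp["n_reps"], seed=cfg.seed + 101,
    )
    splice_path = out / "splice_assay.tsv"
    splice.to_csv(splice_path, sep="\t", index=False)
    written.append(splice_path)

    pr = p["promoter"]
    seq, plant_map = synthetic_data.simulate_promoter(
        synthetic_data.PromoterSimConfig(
            length_bp=pr["length_bp"], gc_fraction=pr["gc_fraction"],
            plants=[synthetic_data.MotifPlant(pl["motif"], count=pl.get("count"),
                                              positions=pl.get("positions"))
                    for pl in pr["plants"]],
            seed=cfg.seed + 202,
        ))
    fasta = out / "promoters.fasta"
    with open(fasta, "w") as fh:
        fh.write(">synthetic|simulated|ups\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
    written.append(fasta)
    plants_path = out / "promoter_plants.tsv"
    pd.DataFrame(plant_map, columns=["motif", "position", "strand"]).to_csv(
        plants_path, sep="\t", index=False)
    written.append(plants_path)
    return written


def _stage_activity(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params["activity"]
    act_sim = cfg.params["simulate"]["activity"]
    ds = locomotor.read_monitor_file(
        out / "monitor.txt",
        schedule_segments=[(1, LightSchedule.parse(act_sim["schedule"]))],
        temperature_label=act_sim["temperature"],
    )
    ds.counts = ds.counts[: act_sim["n_flies"]]
    ds.fly_ids = ds.fly_ids[: act_sim["n_flies"]]
    day_range = tuple(p["day_range"])
    profile = locomotor.daily_profile(ds, day_range, p["smooth_factor"])
    totals = locomotor.total_daily_activity(ds, day_range)
    calls = []
    for f in range(ds.n_flies):
        pg = locomotor.chi_square_periodogram(
            ds.series(f), tuple(p["periodogram_range"]), p["alpha"],
            ds.bin_minutes)
        calls.append(locomotor.classify_rhythmicity(pg, ds.fly_ids[f]))
    summary = locomotor.free_running_summary(
        calls, [f"{act_sim['schedule']}_{act_sim['temperature']}"] * len(calls))
    written = []
    for name, df in [("daily_profile.tsv", profile),
                     ("activity_totals.tsv", totals),
                     ("rhythmicity_summary.tsv", summary)]:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def _stage_qpcr(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params["qpcr"]
    cq = pd.read_csv(out / "cq_table.tsv", sep="\t",
                     dtype={"condition": str})
    collapsed = qpcr.collapse_technical(cq, max_spread=p["max_spread"],
                                        ref_gene=p["ref_gene"])
    genes = sorted(set(cq["gene"]) - {p["ref_gene"]})
    series_rows, phase_rows, series_list = [], [], []
    for g in genes:
        series = qpcr.relative_expression(collapsed, g, p["ref_gene"],
                                          efficiency=p["efficiency"])
        series_list.append(series)
        series_rows.append(series.points.assign(gene=g))
        for cond in series.conditions():
            est = qpcr.peak_phase(series, p["phase_method"], condition=cond)
            phase_rows.append({"gene": g, "condition": cond,
                               "peak_zt": est.peak_zt, "method": est.method,
                               "cycling": est.cycling})
    cyc = qpcr.cycling_tests(series_list,
                             condition=series_list[0].conditions()[0]) \
        if series_list else pd.DataFrame()

    splice = pd.read_csv(out / "splice_assay.tsv", sep="\t",
                         dtype={"condition": str})
    sp_summary, sp_pairs = qpcr.splicing_efficiency(splice)

    written = []
    for name, df in [
        ("relative_expression.tsv", pd.concat(series_rows, ignore_index=True)
         if series_rows else pd.DataFrame()),
        ("peak_phases.tsv", pd.DataFrame(phase_rows)),
        ("cycling_tests.tsv", cyc),
        ("splicing_summary.tsv", sp_summary),
        ("splicing_pairwise.tsv", sp_pairs),
    ]:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def _stage_motifs(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params["motifs"]
    regions = motifscan.read_promoter_fasta(out / "promoters.fasta")
    motifs = [motifscan.Motif(n, i) for n, i in p["motif_set"].items()]
    background = None if p["background"] == "uniform" else p["background"]
    table = motifscan.enrichment_table(regions, motifs, background=background)
    written = []
    path = out / "motif_enrichment.tsv"
    table.to_csv(path, sep="\t", index=False)
    written.append(path)
    for region in regions:
        annotations = motifscan.position_map(region, motifs)
        bed = out / f"positions_{region.gene}_{region.region_kind}.bed"
        motifscan.write_position_bed(region, annotations, bed)
        written.append(bed)
    return written


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "activity": _stage_activity,
    "qpcr": _stage_qpcr,
    "motifs": _stage_motifs,
}


def run(cfg: RunConfig) -> RunManifest:
    """Execute the configured stages in dependency order and write a manifest.

    Checksums of all stage outputs are recorded; for a fixed config and
    seed they are identical across runs.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    stage_files: dict[str, dict[str, str]] = {}
    ordered = [s for s in STAGES if s in cfg.stages]
    for stage in ordered:
        written = _STAGE_FUNCS[stage](cfg, out)
        stage_files[stage] = {p.name: _sha256(p) for p in written}
    config_blob = json.dumps(
        {"seed": cfg.seed, "stages": ordered, "params": cfg.params},
        sort_keys=True).encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_blob).hexdigest(),
        seed=cfg.seed,
        version=__version__,
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
        stage_files=stage_files,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
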