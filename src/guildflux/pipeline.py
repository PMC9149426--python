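"""End-to-end orchestration: ingest → rates → partition → QC → summaries.

``run_pipeline`` composes the whole analysis into one reproducible run: fit
per-bottle slopes, average them into per-treatment slopes per site × assay,
apply the inhibitor-difference partition with bootstrap SEMs, compute IAR
records where the combined treatment exists, summarize transect-level guild
contributions, cross-validate the archaeal estimate where the simvastatin
treatment exists, and regress gene abundances on activities where a gene
table is supplied. All outputs are plain CSV/JSON plus a text report and a
run manifest (config echo, seed, input/output checksums); a rerun from the
same inputs and config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import GuildfluxError, InsufficientPairsError
from .genes import activity_table, correlation_matrix, regress_gene_on_activity, regressions_to_frame
from .io import rates_frame, read_environment, read_genes, read_measurements
from .kinetics import fit_rate, qc_linearity
from .partition import (
    DEFAULT_IAR_BAND,
    DEFAULT_TOTAL_FLOOR,
    GUILDS,
    GuildPartition,
    TreatmentSlopes,
    compute_iar,
    partition_activity,
    propagate_uncertainty,
    summarize_contributions,
    verify_archaeal_methods,
)


@dataclass(frozen=True)
class RunConfig:
    measurements: str
    outdir: str
    genes: str | None = None
    environment: str | None = None
    clamp: bool = True
    min_r2: float = 0.9
    iar_band: tuple[float, float] = DEFAULT_IAR_BAND
    contribution_mode: str = "pooled"
    total_floor: float = DEFAULT_TOTAL_FLOOR
    n_boot: int = 1000
    seed: int = 0
    transform: str = "log10_plus1"
    pooling: str = "site_mean"
    bh_correct: bool = False
    archaeal_test: str = "wilcoxon"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_treatment_slopes(rates: pd.DataFrame) -> list[TreatmentSlopes]:
    """Collapse replicate-level slopes into per-treatment means per site × assay.

    Replicate-level values are retained for bootstrap uncertainty. Bottles are
    separate across treatments, so no pairing is attempted.
    """
    out = []
    for (site, assay), grp in rates.groupby(["site_id", "assay"], sort=True):
        reps = {t: tuple(sub["k"]) for t, sub in grp.groupby("treatment")}
        means = {t: float(np.mean(v)) for t, v in reps.items()}
        required = ("control", "bactericide", "fungicide", "sterilized")
        if any(t not in means for t in required):
            continue
        out.append(
            TreatmentSlopes(
                site_id=str(site),
                assay=str(assay),
                k_control=means["control"],
                k_bactericide=means["bactericide"],
                k_fungicide=means["fungicide"],
                k_sterilized=means["sterilized"],
                k_combined=means.get("combined"),
                k_archaeal_inhibitor=means.get("archaeal_inhibitor"),
                replicates=reps,
            )
        )
    return out


def partition_frame(partitions: list[GuildPartition]) -> pd.DataFrame:
    rows = []
    for p in partitions:
        for g in GUILDS:
            rows.append(
                {
                    "site_id": p.site_id,
                    "assay": p.assay,
                    "component": g,
                    "raw": p.raw[g],
                    "clamped": p.clamped[g],
                    "sem": (p.sem or {}).get(g, float("nan")),
                    "clamp_flag": p.clamp_flags[g],
                    "total": p.total,
                }
            )
    return pd.DataFrame(rows)


def _report_text(partitions: list[GuildPartition], summaries: dict) -> str:
    """Per-site stacked contribution table plus transect summaries."""
    lines = ["guildflux run report", "=" * 60, ""]
    for assay in sorted({p.assay for p in partitions}):
        lines.append(f"[{assay}] per-site activities (ug N / g dry soil / h)")
        lines.append(
            f"{'site':<10}{'total':>9}{'bact':>9}{'fung':>9}{'arch':>9}{'abio':>9}  stacked %"
        )
        for p in [q for q in partitions if q.assay == assay]:
            pct = {
                g: (p.clamped[g] / p.total * 100.0 if p.total > 0 else float("nan"))
                for g in GUILDS
            }
            stack = "/".join(f"{pct[g]:.0f}" for g in GUILDS)
            lines.append(
                f"{p.site_id:<10}{p.total:>9.3f}"
                + "".join(f"{p.clamped[g]:>9.3f}" for g in GUILDS)
                + f"  {stack}"
            )
        if assay in summaries:
            s = summaries[assay]
            lines.append(
                f"  transect ({s['mode']}): "
                + ", ".join(f"{g} {s['percentages'][g]:.1f}%" for g in GUILDS)
            )
        lines.append("")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Any stage failure aborts with the stage name in the raised message; no
    partial manifest is written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        series = read_measurements(config.measurements)

        stage = "rates"
        estimates = [fit_rate(s) for s in series]
        qc = [qc_linearity(e, config.min_r2).passed for e in estimates]
        rates = rates_frame(series, estimates, qc)
        rates.to_csv(outdir / "rates.csv", index=False)

        stage = "partition"
        slope_sets = build_treatment_slopes(rates)
        partitions = []
        for i, s in enumerate(slope_sets):
            p = partition_activity(s, clamp=config.clamp)
            sem = propagate_uncertainty(
                s.replicates,
                n_boot=config.n_boot,
                seed=config.seed + i,
                clamp=config.clamp,
                site_id=s.site_id,
                assay=s.assay,
            )
            partitions.append(dataclasses.replace(p, sem=sem))
        partition_frame(partitions).to_csv(outdir / "partition.csv", index=False)

        stage = "iar"
        iar_rows = []
        for s in slope_sets:
            if s.k_combined is None:
                continue
            try:
                r = compute_iar(s, config.iar_band)
            except GuildfluxError:
                continue
            iar_rows.append(
                {"site_id": r.site_id, "assay": r.assay, "a": r.a, "b": r.b,
                 "c": r.c, "d": r.d, "iar": r.iar, "pass": r.passed}
            )
        iar_skipped = not iar_rows
        if iar_rows:
            pd.DataFrame(iar_rows).to_csv(outdir / "iar.csv", index=False)

        stage = "contributions"
        summaries = {}
        for assay in sorted({p.assay for p in partitions}):
            subset = [p for p in partitions if p.assay == assay]
            s = summarize_contributions(
                subset,
                mode=config.contribution_mode,
                n_boot=config.n_boot,
                seed=config.seed,
                floor=config.total_floor,
            )
            summaries[assay] = {
                "mode": s.mode,
                "percentages": dict(s.percentages),
                "ci": {g: list(v) for g, v in s.ci.items()},
                "n_sites": s.n_sites,
                "excluded_sites": list(s.excluded_sites),
                "n_boot": s.n_boot,
                "seed": s.seed,
            }
        with open(outdir / "contributions.json", "w") as fh:
            json.dump(summaries, fh, indent=2, sort_keys=True)
            fh.write("\n")

        stage = "archaeal-verification"
        verification = {}
        for assay in sorted({s.assay for s in slope_sets}):
            with_inh = [
                s for s in slope_sets
                if s.assay == assay and s.k_archaeal_inhibitor is not None
            ]
            if len(with_inh) < 3:
                continue
            try:
                v = verify_archaeal_methods(with_inh, test=config.archaeal_test)
            except InsufficientPairsError:
                continue
            verification[assay] = {
                "site_ids": list(v.site_ids),
                "method1_difference": list(v.method1),
                "method2_specific_inhibitor": list(v.method2),
                "test": v.test,
                "statistic": v.statistic,
                "p_value": v.p_value,
                "methods_agree": v.methods_agree,
            }
        if verification:
            with open(outdir / "verification.json", "w") as fh:
                json.dump(verification, fh, indent=2, sort_keys=True)
                fh.write("\n")

        stage = "gene-regressions"
        if config.genes:
            genes = read_genes(config.genes)
            acts = activity_table(partitions)
            results = regress_gene_on_activity(
                genes, acts, transform=config.transform,
                pooling=config.pooling, bh_correct=config.bh_correct,
            )
            regressions_to_frame(results).to_csv(outdir / "gene_regressions.csv", index=False)
            if config.environment:
                env = read_environment(config.environment)
                correlation_matrix(genes, env, transform=config.transform).to_csv(
                    outdir / "gene_env_correlations.csv", index=False
                )

        stage = "report"
        report = _report_text(partitions, summaries)
        (outdir / "report.txt").write_text(report)
    except GuildfluxError as exc:
        raise GuildfluxError(f"stage {stage!r} failed: {exc}") from exc

    stage = "manifest"
    inputs = {"measurements": config.measurements}
    if config.genes:
        inputs["genes"] = config.genes
    if config.environment:
        inputs["environment"] = config.environment
    outputs = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "guildflux_version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "input_checksums": {k: _sha256(Path(v)) for k, v in inputs.items()},
        "output_checksums": {name: _sha256(outdir / name) for name in outputs},
        "iar_skipped": iar_skipped,
        "stages_completed": True,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
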