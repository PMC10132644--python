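"""End-to-end runs: simulate a fixture bundle, analyse it, render reports.

The demo scenario emulates a liquid-culture escape experiment with a
seed-mismatched crRNA: a wild-type phage population with a trace of
preexisting escape mutants (a PAM mutation and a seed mutation) is
propagated under strong selection, sampled at several timepoints in two
replicates, and sequenced as paired amplicon reads alongside a
non-targeted control population.  Everything is synthetic and seeded.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amplicon import calls_to_frame, classify_pairs, status_counts, tabulate
from .stats import haplotypes_from_calls, nucleotide_diversity, timecourse_table, zscores
from .synthetic import (
    GenotypeSpec,
    emit_amplicon_reads,
    read_fastq,
    sample_population,
    simulate_population,
    write_fastq,
)
from .targets import TargetSpec


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class SampleEntry:
    sample_id: str
    r1: str
    r2: str
    role: str  # "experimental" | "control"
    timepoint: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ("experimental", "control"):
            raise ConfigError(f"sample {self.sample_id}: role must be experimental or control")


@dataclass
class RunConfig:
    """One analysis run: a target, a sample manifest, and analysis toggles."""

    target: TargetSpec
    samples: list[SampleEntry]
    seed: int = 0
    deletion_convention: str = "3prime_adjacent"
    sigma_ddof: int = 1
    require_concordance: bool = True
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        roles = {s.role for s in self.samples}
        if "experimental" in roles and "control" not in roles:
            raise ConfigError(
                "experimental samples need at least one control sample for Z-scores"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        tgt = raw["target"]
        target = TargetSpec.from_window(
            amplicon_reference=tgt["amplicon_reference"],
            window_start=int(tgt["window_start"]),
            pam_side=tgt["pam_side"],
            pam_length=int(tgt.get("pam_length", 4)),
            protospacer_length=int(tgt.get("protospacer_length", 20)),
            anchor_length=int(tgt.get("anchor_length", 12)),
            genome_offset=int(tgt.get("genome_offset", 0)),
        )
        samples = [SampleEntry(**s) for s in raw.get("samples", [])]
        base = Path(path).parent
        for s in samples:
            s.r1 = str((base / s.r1) if not Path(s.r1).is_absolute() else s.r1)
            s.r2 = str((base / s.r2) if not Path(s.r2).is_absolute() else s.r2)
        analysis = raw.get("analysis", {})
        cfg = cls(
            target=target,
            samples=samples,
            seed=int(raw.get("seed", 0)),
            deletion_convention=analysis.get("deletion_convention", "3prime_adjacent"),
            sigma_ddof=int(analysis.get("sigma_ddof", 1)),
            require_concordance=bool(analysis.get("require_concordance", True)),
            raw=raw,
        )
        missing = [s.r1 for s in samples if not Path(s.r1).exists()]
        missing += [s.r2 for s in samples if not Path(s.r2).exists()]
        if missing:
            raise ConfigError(f"missing input files: {missing}")
        return cfg


# ---------------------------------------------------------------------------
# demo scenario


def make_demo_target(seed: int = 20230415, amplicon_length: int = 104,
                     window_start: int = 40) -> TargetSpec:
    """A synthetic Cas12a-style target window on a synthetic amplicon.

    The sequence is a generated stand-in for a phage intergenic target
    region, not a real genome segment: a random ACGT amplicon whose window
    starts with a TTTA PAM (5' side), with 8-nt flank anchors.  The
    construction retries seeds until the anchors are unique in the
    amplicon, so the result is deterministic.
    """
    attempt = seed
    while True:
        rng = np.random.default_rng(attempt)
        bases = rng.choice(list("ACGT"), size=amplicon_length)
        bases[window_start : window_start + 4] = list("TTTA")
        ref = "".join(bases)
        try:
            return TargetSpec.from_window(
                amplicon_reference=ref,
                window_start=window_start,
                pam_side="5prime",
                pam_length=4,
                protospacer_length=20,
                anchor_length=8,
            )
        except Exception:
            attempt += 1


def demo_genotypes(spec: TargetSpec, selection: bool = True) -> list[GenotypeSpec]:
    """Wild type plus two preexisting escape mutants (PAM -2 and seed 2).

    Under selection the wild type propagates at weight 0.02 (residual
    escape from cleavage) while both mutants propagate at weight 1.0;
    without selection all weights are equal, emulating the non-targeted
    control culture.
    """
    wt = spec.reference_window
    off_pam = spec.offset_of(-2)
    off_seed = spec.offset_of(2)

    def sub(window: str, off: int) -> str:
        alt = {"A": "T", "T": "C", "C": "A", "G": "T"}[window[off]]
        return window[:off] + alt + window[off + 1 :]

    pam_mut = sub(wt, off_pam)
    seed_mut = sub(wt, off_seed)
    w_wt = 0.02 if selection else 1.0
    w_mut = 1.0
    return [
        GenotypeSpec(haplotype=wt, initial_frequency=0.998, survival_weight=w_wt, name="WT"),
        GenotypeSpec(haplotype=pam_mut, initial_frequency=0.001, survival_weight=w_mut, name="PAM_mut"),
        GenotypeSpec(haplotype=seed_mut, initial_frequency=0.001, survival_weight=w_mut, name="seed_mut"),
    ]


def run_simulate(
    outdir,
    seed: int = 0,
    n_generations: int = 6,
    sample_generations: tuple[int, ...] = (0, 2, 4, 6),
    pop_size: int = 20000,
    n_replicates: int = 2,
    reads_per_sample: int = 2000,
    read_length: int = 75,
    seq_error_rate: float = 0.001,
    discordance_rate: float = 0.0,
    population_error_rate: float = 1e-5,
) -> Path:
    """Generate the demo escape-scenario fixture bundle.

    Writes paired FASTQs for each (replicate × generation) experimental
    sample and for the non-targeted control replicates, truth tables of the
    planted genotypes and population trajectories, and an analysis
    configuration consumable by :func:`run_amplicon`.  Returns the path of
    the written config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = make_demo_target()
    genotypes = demo_genotypes(spec, selection=True)
    control_genotypes = demo_genotypes(spec, selection=False)
    rng = np.random.default_rng(seed)

    samples = []
    truth_frames = []
    traj_rows = []
    for rep in range(1, n_replicates + 1):
        ts = simulate_population(
            genotypes, n_generations=n_generations, pop_size=pop_size,
            error_rate=population_error_rate, seed=int(rng.integers(2**31 - 1)),
        )
        for gen, freqs in zip(ts.timepoints, ts.frequencies):
            for hap, f in freqs.items():
                traj_rows.append({"replicate": rep, "generation": gen, "haplotype": hap, "frequency": f})
        for gen in sample_generations:
            freqs = ts.frequencies[ts.timepoints.index(gen)]
            counts = sample_population(freqs, reads_per_sample, seed=int(rng.integers(2**31 - 1)))
            sid = f"exp_rep{rep}_gen{gen}"
            r1, r2, truth = emit_amplicon_reads(
                counts, spec, read_length=read_length,
                seq_error_rate=seq_error_rate, discordance_rate=discordance_rate,
                seed=int(rng.integers(2**31 - 1)),
            )
            write_fastq(r1, outdir / f"{sid}_R1.fastq")
            write_fastq(r2, outdir / f"{sid}_R2.fastq")
            truth["sample_id"] = sid
            truth_frames.append(truth)
            samples.append(
                {"sample_id": sid, "r1": f"{sid}_R1.fastq", "r2": f"{sid}_R2.fastq",
                 "role": "experimental", "timepoint": float(gen)}
            )
    # non-targeted control: the same starting population propagated without
    # selection, sampled at the final generation
    for rep in range(1, n_replicates + 1):
        ts = simulate_population(
            control_genotypes, n_generations=n_generations, pop_size=pop_size,
            error_rate=population_error_rate, seed=int(rng.integers(2**31 - 1)),
        )
        counts = sample_population(ts.final_frequencies(), reads_per_sample,
                                   seed=int(rng.integers(2**31 - 1)))
        sid = f"ctl_rep{rep}"
        r1, r2, truth = emit_amplicon_reads(
            counts, spec, read_length=read_length,
            seq_error_rate=seq_error_rate, discordance_rate=discordance_rate,
            seed=int(rng.integers(2**31 - 1)),
        )
        write_fastq(r1, outdir / f"{sid}_R1.fastq")
        write_fastq(r2, outdir / f"{sid}_R2.fastq")
        truth["sample_id"] = sid
        truth_frames.append(truth)
        samples.append(
            {"sample_id": sid, "r1": f"{sid}_R1.fastq", "r2": f"{sid}_R2.fastq",
             "role": "control", "timepoint": float(n_generations)}
        )

    pd.concat(truth_frames).to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    pd.DataFrame(traj_rows).to_csv(outdir / "truth_trajectory.tsv", sep="\t", index=False)
    with open(outdir / "target.fasta", "w") as fh:
        fh.write(">synthetic_demo_amplicon\n" + spec.amplicon_reference + "\n")

    config = {
        "seed": seed,
        "target": {
            "amplicon_reference": spec.amplicon_reference,
            "window_start": spec.window_start,
            "pam_side": spec.pam_side,
            "pam_length": spec.pam_length,
            "protospacer_length": spec.protospacer_length,
            "anchor_length": len(spec.flank_anchor_left),
            "genome_offset": spec.genome_offset,
        },
        "analysis": {"deletion_convention": "3prime_adjacent", "sigma_ddof": 1,
                     "require_concordance": True},
        "samples": samples,
    }
    config_path = outdir / "analysis_config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config_path


# ---------------------------------------------------------------------------
# analysis run


def _load_pairs(entry: SampleEntry) -> list[tuple[str, str, str]]:
    r1 = read_fastq(entry.r1)
    r2 = read_fastq(entry.r2)
    if len(r1) != len(r2):
        raise ConfigError(f"sample {entry.sample_id}: R1/R2 record counts differ")
    return [(a.read_id, a.sequence, b.sequence) for a, b in zip(r1, r2)]


def run_amplicon(config: RunConfig, outdir) -> dict:
    """Classify every sample, tabulate, and compute enrichment statistics.

    Writes per-sample classification and position-proportion TSVs, a
    Z-score table (combined and per-experimental-sample columns, final
    timepoint vs controls), per-sample nucleotide diversity, the
    fraction-mutated time course over experimental replicates, and a run
    manifest with read-count accounting.  Returns the result objects for
    programmatic use.
    """
    outdir = Path(outdir)
    (outdir / "classification").mkdir(parents=True, exist_ok=True)
    spec = config.target
    calls_by_sample = {}
    matrices = {}
    accounting = {}
    for entry in config.samples:
        calls = classify_pairs(_load_pairs(entry), spec,
                               require_concordance=config.require_concordance)
        calls_by_sample[entry.sample_id] = calls
        counts = status_counts(calls)
        accounting[entry.sample_id] = counts
        calls_to_frame(calls).to_csv(
            outdir / "classification" / f"{entry.sample_id}.tsv", sep="\t", index=False
        )
        matrices[entry.sample_id] = tabulate(
            calls, spec, sample_id=entry.sample_id,
            deletion_convention=config.deletion_convention,
        )
    matrix_frame = pd.DataFrame(
        {sid: m.proportions for sid, m in matrices.items()}
    )
    matrix_frame.index.name = "position"
    matrix_frame.to_csv(outdir / "position_proportions.tsv", sep="\t")

    controls = [s for s in config.samples if s.role == "control"]
    experimental = [s for s in config.samples if s.role == "experimental"]
    results: dict = {"matrices": matrices, "calls": calls_by_sample}

    if experimental and controls:
        final_t = max(s.timepoint for s in experimental)
        final_exp = [s for s in experimental if s.timepoint == final_t]
        ctl_mats = [matrices[s.sample_id] for s in controls]
        combined = zscores([matrices[s.sample_id] for s in final_exp], ctl_mats,
                           ddof=config.sigma_ddof)
        per_sample = {
            s.sample_id: zscores([matrices[s.sample_id]], ctl_mats, ddof=config.sigma_ddof)
            for s in final_exp
        }
        ztab = pd.DataFrame({"Z_combined": combined.z})
        for sid, zm in per_sample.items():
            ztab[f"Z_{sid}"] = zm.z
        ztab.index.name = "position"
        ztab.to_csv(outdir / "zscores.tsv", sep="\t")
        results["zscores"] = combined
        results["zscores_per_sample"] = per_sample

    div_rows = []
    for entry in config.samples:
        table = haplotypes_from_calls(calls_by_sample[entry.sample_id], spec)
        div_rows.append(
            {"sample_id": entry.sample_id, "role": entry.role,
             "timepoint": entry.timepoint,
             "diversity": nucleotide_diversity(table),
             "n_haplotypes": table.n}
        )
    diversity_frame = pd.DataFrame(div_rows)
    diversity_frame.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    results["diversity"] = diversity_frame

    if experimental:
        by_time: dict[float, list] = {}
        for s in experimental:
            by_time.setdefault(s.timepoint, []).append(calls_by_sample[s.sample_id])
        tc = timecourse_table(sorted(by_time.items()))
        tc.to_csv(outdir / "fraction_mutated.tsv", sep="\t", index=False)
        results["timecourse"] = tc

    manifest = {
        "package": "phagescape",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config.raw, sort_keys=True).encode()
        ).hexdigest(),
        "read_accounting": accounting,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results


def render_report(config: RunConfig, results: dict, outdir) -> list[Path]:
    """Z-score heat map and fraction-mutated time course images."""
    from .report import timecourse_plot, zscore_heatmap

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if "zscores_per_sample" in results:
        path = outdir / "zscore_heatmap.png"
        zscore_heatmap(results["zscores_per_sample"], path)
        written.append(path)
    if "timecourse" in results:
        path = outdir / "fraction_mutated.png"
        timecourse_plot(results["timecourse"], path)
        written.append(path)
    return written
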