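"""Run configuration and end-to-end orchestration.

A run simulates a four-condition depletion experiment (untreated,
SET1-depleted, ZC3H4-depleted, double-depleted), sequences replicate
libraries with spike-in, calibrates them, runs spike-anchored
differential testing for each contrast, builds decile and epistasis
summaries, and profiles attenuation around TSSs.  Every stage draws
randomness only from named substreams of the master seed, so re-running
a configuration reproduces the output tree byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import annotation, calibration, diffexpr, io, profiles, simulate

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "DEFAULT_CONDITIONS"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


DEFAULT_CONDITIONS = (
    {"label": "UNT", "s": 1.0, "z": 1.0},
    {"label": "dSET1", "s": 0.0, "z": 1.0},
    {"label": "dZC3H4", "s": 1.0, "z": 0.0},
    {"label": "dBOTH", "s": 0.0, "z": 0.0},
)


@dataclass
class RunConfig:
    """Configuration of one simulated-and-analysed run."""

    seed: int = 0
    n_genes: int = 1000
    n_enhancers: int | None = None
    n_spike: int = 200
    cgi_fraction: float = 0.7
    replicates: int = 3
    depth: float = 2e6
    mixing_ratio: float = 0.25
    assay: str = "cTT"
    t_since_depletion: float = 2.0
    conditions: tuple = DEFAULT_CONDITIONS
    contrasts: tuple = (("UNT", "dSET1"), ("UNT", "dZC3H4"), ("UNT", "dBOTH"))
    alpha: float = 0.05
    min_fc: float = 1.5
    min_mean: float = 1.0
    expressed_rpkm: float = 0.5
    bin_width: int = 50
    flank: int = 5000
    kinetics: dict = field(default_factory=dict)
    write_tracks: bool = False

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.min_fc <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        for key in ("conditions", "contrasts"):
            if key in raw:
                raw[key] = tuple(
                    tuple(v) if isinstance(v, (list, tuple)) else v for v in raw[key]
                )
        return cls(**raw)

    def kinetic_params(self) -> simulate.KineticParams:
        return simulate.KineticParams(bin_width=self.bin_width, **self.kinetics)


def _condition_specs(cfg: RunConfig) -> list[simulate.ConditionSpec]:
    specs = []
    for c in cfg.conditions:
        c = dict(c)
        specs.append(
            simulate.ConditionSpec(
                label=c["label"],
                s=float(c.get("s", 1.0)),
                z=float(c.get("z", 1.0)),
                t_since_depletion=float(c.get("t", cfg.t_since_depletion)),
                assay=c.get("assay", cfg.assay),
                mixing_ratio=float(c.get("mixing_ratio", cfg.mixing_ratio)),
                depth=float(c.get("depth", cfg.depth)),
            )
        )
    return specs


def _gene_bed(genome: simulate.GenomeSpec) -> annotation.RegionSet:
    rows = [
        {
            "chrom": g.chrom,
            "start": g.start,
            "end": g.end,
            "id": g.id,
            "score": int(round(1000 * g.set1_occupancy)),
            "strand": g.strand,
        }
        for g in genome.genes
    ]
    return annotation.RegionSet(pd.DataFrame(rows), role="gene")


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute simulate -> calibrate -> test -> profile and write results.

    Returns the summary dictionary (also written as summary.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "INCOMPLETE"
    marker.write_text("run in progress\n")
    log: list[dict] = []

    def stage(name: str):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    kin = cfg.kinetic_params()

    # ---- simulate ------------------------------------------------------
    genome = stage("simulate")(
        simulate.build_genome,
        cfg.n_genes,
        cfg.n_enhancers,
        cfg.n_spike,
        seed=cfg.seed,
        cgi_fraction=cfg.cgi_fraction,
        bin_width=cfg.bin_width,
    )
    conditions = _condition_specs(cfg)
    expectations = {
        c.label: stage("simulate")(simulate.expected_signals, genome, c, kin)
        for c in conditions
    }
    samples: list[calibration.SampleCounts] = []
    design: dict[str, str] = {}
    for c in conditions:
        for rep in range(1, cfg.replicates + 1):
            sid = f"{c.label}_rep{rep}"
            sc, inp = stage("simulate")(
                simulate.sample_counts, expectations[c.label], c, cfg.seed, sid
            )
            samples.append(sc)
            design[sid] = c.label
            if inp is not None:
                samples.append(inp)
    log.append({"stage": "simulate", "seed": cfg.seed, "n_genes": cfg.n_genes})

    genes_bed = _gene_bed(genome)
    io.write_regions(genes_bed, outdir / "genes.bed")
    io.write_counts(samples, outdir / "counts.tsv")
    sheet = pd.DataFrame(
        [
            {"sample_id": sid, "condition": cond}
            for sid, cond in design.items()
        ]
    )
    sheet.to_csv(outdir / "conditions.tsv", sep="\t", index=False)
    if cfg.write_tracks:
        for label in (conditions[0].label, conditions[1].label):
            for st, suffix in (("+", "plus"), ("-", "minus")):
                io.write_track(
                    expectations[label].tracks[st],
                    outdir / f"{label}.{suffix}.bedGraph",
                )

    # ---- calibrate -----------------------------------------------------
    main_samples = [sc for sc in samples if sc.sample_id in design]
    calres = stage("calibrate")(calibration.rna_calibration_factors, main_samples)
    spike_mat = pd.DataFrame({sc.sample_id: sc.spike for sc in main_samples})
    target_mat = pd.DataFrame({sc.sample_id: sc.target for sc in main_samples})
    sf = stage("calibrate")(calibration.spike_size_factors, spike_mat)
    io.write_json(
        {"calibration": calres, "size_factors": sf, "seed": cfg.seed},
        outdir / "factors.json",
    )
    log.append({"stage": "calibrate", "reference": calres.reference})

    # ---- differential testing -----------------------------------------
    design_s = pd.Series(design)
    gene_ids = [g.id for g in genome.genes]
    gene_lengths = pd.Series({g.id: g.length for g in genome.genes})
    gene_counts = target_mat.loc[gene_ids]
    rpkm_all = diffexpr.rpkm(
        gene_counts, gene_lengths, sf.factors
    )
    unt_cols = design_s.index[design_s == conditions[0].label]
    unt_rpkm = rpkm_all[unt_cols].mean(axis=1)
    expressed = unt_rpkm.index[unt_rpkm > cfg.expressed_rpkm]

    de_tables: dict[str, pd.DataFrame] = {}
    class_counts: dict[str, dict[str, int]] = {}
    decile_tables: dict[str, pd.Series] = {}
    deciles = annotation.expression_deciles(unt_rpkm)
    for ref, alt in cfg.contrasts:
        table = stage("diffexp")(
            diffexpr.run_differential,
            gene_counts,
            sf.factors,
            design_s,
            (ref, alt),
            alpha=cfg.alpha,
            min_fc=cfg.min_fc,
            min_mean=cfg.min_mean,
        )
        labels, counts_summary = diffexpr.classify_genes(
            table, expressed, alpha=cfg.alpha, min_fc=cfg.min_fc
        )
        table["class"] = labels
        name = f"{alt}_vs_{ref}"
        table.to_csv(outdir / f"de_{name}.tsv", sep="\t")
        de_tables[name] = table
        class_counts[name] = counts_summary
        decile_tables[name] = table["log2FC"].groupby(deciles).median()
    log.append({"stage": "diffexp", "contrasts": [f"{a}_vs_{r}" for r, a in cfg.contrasts]})

    # ---- profiles and epistasis ---------------------------------------
    unt = expectations[conditions[0].label]
    summary_profiles = {}
    attenuation = None
    set1_label = next((c.label for c in conditions if c.s == 0 and c.z > 0), None)
    if set1_label is not None:
        dep = expectations[set1_label]
        mats = {}
        for label, exp in (("unt", unt), ("dep", dep)):
            mats[label] = profiles.coverage_matrix(
                exp.tracks["+"],
                exp.tracks["-"],
                genes_bed,
                upstream=0,
                downstream=min(cfg.flank, 3000),
                strand_mode="sense",
            )
        pc = profiles.default_pseudocount(unt.tracks["+"])
        _, log2_mat = profiles.foldchange_profile(mats["dep"], mats["unt"], pc)
        log2_pm = profiles.ProfileMatrix(
            values=log2_mat,
            mask=mats["unt"].mask,
            region_ids=mats["unt"].region_ids,
            offsets=mats["unt"].offsets,
            bin_width=mats["unt"].bin_width,
        )
        zones = {
            g.id: (0.0, float(z)) if (z := unt.genes.loc[g.id, "zone_len"]) else None
            for g in genome.genes
        }
        attenuation = profiles.attenuation_summary(log2_pm, zones)
        attenuation.to_csv(outdir / "attenuation.tsv", sep="\t")
        protected = unt.genes.index[(unt.genes["o"] > 0.5)]
        summary_profiles["attenuation_in_cgi_fraction"] = float(
            attenuation.loc[protected, "in_cgi"].mean()
        )
        meta = profiles.metaprofile(log2_pm)
        meta.to_csv(outdir / "metaprofile_log2fc.tsv", sep="\t", index=False)

    epistasis = {}
    z_label = next((c.label for c in conditions if c.z == 0 and c.s > 0), None)
    both_label = next((c.label for c in conditions if c.z == 0 and c.s == 0), None)
    if z_label and both_label:
        lfc_z = np.log2(expectations[z_label].genes["F"] / unt.genes["F"])
        lfc_b = np.log2(expectations[both_label].genes["F"] / unt.genes["F"])
        r = float(stats.pearsonr(lfc_z, lfc_b)[0]) if lfc_z.std() > 0 else 1.0
        epistasis = {
            "pearson_r": r,
            "mean_abs_delta": float((lfc_b - lfc_z).abs().mean()),
        }

    summary = {
        "seed": cfg.seed,
        "class_counts": class_counts,
        "decile_median_log2fc": {k: v.to_dict() for k, v in decile_tables.items()},
        "epistasis": epistasis,
        "profiles": summary_profiles,
        "n_expressed": int(len(expressed)),
        "log": log,
    }
    io.write_json(summary, outdir / "summary.json")
    marker.unlink()
    return summary


def tree_checksum(outdir: str | Path) -> str:
    """Checksum of every regular file in a run directory (determinism aid)."""
    outdir = Path(outdir)
    h = hashlib.sha256()
    for p in sorted(outdir.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
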