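"""Config-driven orchestration: simulate -> measure -> extract -> stats.

A run is described by a YAML/dict :class:`RunConfig` (validated up
front), fanned out into deterministic per-stage seeds, and written as a
bundle of CSV tables, a JSON stats summary and a human-readable report.
Every output embeds the seed and a hash of the resolved configuration so
a stored config reproduces its outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import defaults, io, synthetic
from . import cohort_stats as cs
from . import ephys
from .morphometry import measure_cohort
from .solutions import (ACSF_MM, IonicSolution, PIPETTE_KGLUCONATE_MM,
                        ljp_henderson)

__all__ = ["RunConfig", "run_pipeline", "make_fixtures", "stage_seed"]

log = logging.getLogger("aisquant")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``cohorts`` maps a condition label to a dict with keys ``preset``
    (named length preset), optional ``n_animals`` / ``n_per_animal`` /
    ``hemisphere``.  ``comparisons`` lists pairs of condition labels for
    the distribution-shift analysis; ``paired`` lists paired-hemisphere
    designs.
    """

    seed: int = 0
    theta: float = defaults.THETA_DEFAULT
    window_um: float = defaults.SMOOTH_WINDOW_UM
    pixel_size_um: float = 0.21
    psf_sigma_um: float = 0.5
    noise_sd: float = 0.1
    measure_profiles: bool = True
    cohorts: dict = field(default_factory=dict)
    comparisons: list = field(default_factory=list)
    paired: list = field(default_factory=list)
    log_level: str = "INFO"

    def __post_init__(self):
        lo, hi = defaults.THETA_BOUNDS
        if not (lo <= self.theta <= hi):
            raise ValueError(f"theta={self.theta} outside [{lo}, {hi}]")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        self.seed = int(self.seed)
        if self.pixel_size_um <= 0 or self.noise_sd < 0 or self.psf_sigma_um < 0:
            raise ValueError("invalid imaging parameters")
        for name, spec in self.cohorts.items():
            if spec.get("preset") not in synthetic.COHORT_PRESETS:
                raise ValueError(f"unknown preset in cohort '{name}': "
                                 f"{spec.get('preset')!r}")
        known = set(self.cohorts)
        for pair in self.comparisons:
            if len(pair) != 2 or not set(pair) <= known:
                raise ValueError(f"bad comparison {pair!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        allowed = set(cls.__dataclass_fields__)
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def paper_emulation_config(seed: int = 0) -> RunConfig:
    """The bundled long-term-deprivation + EE emulation run."""
    return RunConfig(
        seed=seed,
        cohorts={
            "P15-Ctrl": {"preset": "P15-Ctrl", "n_animals": 6,
                         "n_per_animal": 100},
            "P15-Dep": {"preset": "P15-Dep", "n_animals": 6,
                        "n_per_animal": 100},
        },
        comparisons=[["P15-Ctrl", "P15-Dep"]],
        paired=[{"name": "EE-3h", "ctrl": "EE-Ctrl-3h",
                 "stim": "EE-Stim-3h", "n_animals": 6,
                 "n_per_hemisphere": 100}],
    )


def _measure_condition(lengths, cfg: RunConfig, seed: int, annotations):
    """Ground-truth lengths -> synthetic profiles -> measured lengths."""
    pairs = synthetic.gen_profiles_for_lengths(
        lengths, seed=seed, psf_sigma_um=cfg.psf_sigma_um,
        noise_sd=cfg.noise_sd, pixel_size_um=cfg.pixel_size_um)
    annotated = [(prof, ann) for (prof, _), ann in zip(pairs, annotations)]
    result = measure_cohort(annotated, theta=cfg.theta,
                            window_um=cfg.window_um)
    return result


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute simulate -> measure -> stats and write the report bundle.

    Returns the stats summary dict (also written as ``stats.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    meta = {"seed": config.seed, "config_sha": config.config_hash()}
    summary = {"meta": dict(meta)}

    # --- simulate + measure length cohorts --------------------------------
    tables = {}
    for name, spec in config.cohorts.items():
        sd = stage_seed(config.seed, f"cohort:{name}")
        cohort = synthetic.gen_cohort(
            spec["preset"], seed=sd,
            n_animals=spec.get("n_animals"),
            n_per_animal=spec.get("n_per_animal"),
            condition=name, hemisphere=spec.get("hemisphere", "ctrl"))
        if config.measure_profiles:
            anns = cohort[["ais_id", "animal_id", "condition", "layer",
                           "hemisphere", "cfos"]].to_dict("records")
            res = _measure_condition(
                cohort.length_um.values, config,
                stage_seed(config.seed, f"profiles:{name}"), anns)
            table = res.table
            table["true_length_um"] = cohort.length_um.values
            log.info("cohort %s: %d/%d profiles accepted", name,
                     int(table.qc_pass.sum()), len(table))
        else:
            table = cohort
        tables[name] = table
        io.write_table_csv(outdir / f"cohort_{name}.csv", table, meta)

    # --- distribution-shift statistics ------------------------------------
    length_col = "length_um"
    summaries = {}
    for name, table in tables.items():
        acc = table[table.qc_pass][length_col] if "qc_pass" in table \
            else table[length_col]
        ds = cs.summarize_distribution(acc.values)
        summaries[name] = {"median_um": ds.median_um, "fwhm_um": ds.fwhm_um,
                           "n": ds.n}
    summary["distributions"] = summaries

    comparisons = {}
    for a, b in config.comparisons:
        ta, tb = tables[a], tables[b]
        xa = ta[ta.qc_pass][length_col].values if "qc_pass" in ta else ta[length_col].values
        xb = tb[tb.qc_pass][length_col].values if "qc_pass" in tb else tb[length_col].values
        ks = cs.ks_two_sample(xa, xb)
        comparisons[f"{a} vs {b}"] = {
            "test": ks.test_name, "D": ks.statistic, "p": ks.p_value,
            "median_shift_um": ks.effect, "n": ks.n_per_group}
    summary["comparisons"] = comparisons

    # --- paired EE designs -------------------------------------------------
    paired = {}
    for spec in config.paired:
        sd = stage_seed(config.seed, f"paired:{spec['name']}")
        cohort = synthetic.gen_paired_ee_cohort(
            seed=sd, n_animals=spec.get("n_animals", 6),
            n_per_hemisphere=spec.get("n_per_hemisphere", 100),
            ctrl_preset=spec["ctrl"], stim_preset=spec["stim"])
        io.write_table_csv(outdir / f"paired_{spec['name']}.csv", cohort, meta)
        diff, res = cs.paired_hemisphere_test(cohort)
        paired[spec["name"]] = {
            "mean_paired_difference_um": diff, "test": res.test_name,
            "p": res.p_value, "n_animals": spec.get("n_animals", 6)}
    summary["paired"] = paired

    # --- junction potential of the standard recipes ------------------------
    summary["ljp_mV"] = ljp_henderson(
        IonicSolution.from_recipe(PIPETTE_KGLUCONATE_MM, "pipette"),
        IonicSolution.from_recipe(ACSF_MM, "ACSF", pH=7.4))

    with open(outdir / "stats.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    _write_report(outdir / "report.md", config, summary)
    return summary


def _write_report(path, config: RunConfig, summary: dict):
    lines = [
        "# AIS cohort analysis report",
        f"seed: {config.seed}  config: {summary['meta']['config_sha']}", "",
        "## Length distributions", ""]
    for name, d in summary.get("distributions", {}).items():
        lines.append(f"- {name}: median {d['median_um']:.1f} um, "
                     f"FWHM {d['fwhm_um']:.1f} um (n={d['n']})")
    lines += ["", "## Distribution shifts", ""]
    for name, c in summary.get("comparisons", {}).items():
        lines.append(f"- {name}: D={c['D']:.3f}, p={c['p']:.2e}, "
                     f"median shift {c['median_shift_um']:+.1f} um")
    lines += ["", "## Paired hemisphere designs", ""]
    for name, c in summary.get("paired", {}).items():
        lines.append(f"- {name}: mean paired shortening "
                     f"{c['mean_paired_difference_um']:.2f} um "
                     f"({c['test']}, p={c['p']:.3g})")
    lines += ["", f"Junction potential of the standard recipes: "
              f"{summary['ljp_mV']:.1f} mV", ""]
    Path(path).write_text("\n".join(lines))


def make_fixtures(seed: int = 0, outdir="fixtures") -> Path:
    """Write the deterministic test fixture set (no downloads).

    10 profiles, one image + traced path, one sweep family per protocol,
    one PSC trace and two mini length cohorts, each with a ground-truth
    sidecar table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": seed}

    truth_rows = []
    rng = np.random.default_rng(stage_seed(seed, "fixtures:profiles"))
    for k in range(10):
        truth = synthetic.AISGroundTruth(
            start_um=float(rng.uniform(2, 5)),
            end_um=float(rng.uniform(20, 40)),
            psf_sigma_um=0.5, noise_sd=0.05)
        prof, _ = synthetic.gen_ais_profile(
            truth, seed=stage_seed(seed, f"fixtures:profile{k}"),
            source_id=f"fixture{k:02d}")
        io.write_profile_csv(outdir / f"profile_{k:02d}.csv", prof, meta)
        truth_rows.append({"source_id": prof.source_id,
                           "start_um": truth.start_um,
                           "end_um": truth.end_um,
                           "length_um": truth.length_um})
    io.write_table_csv(outdir / "profile_truth.csv",
                       pd.DataFrame(truth_rows), meta)

    img_truth = synthetic.AISGroundTruth(start_um=4.0, end_um=28.0,
                                         psf_sigma_um=0.4, noise_sd=0.02)
    path_px = np.array([[10.0, 40.0], [150.0, 40.0]])
    img, _ = synthetic.gen_ais_image(img_truth, path_px, (80, 160),
                                     seed=stage_seed(seed, "fixtures:image"))
    io.write_tiff(outdir / "ais_image.tiff", img)
    io.write_path_csv(outdir / "ais_path.csv", path_px, 0.21)

    params = synthetic.SpikeModelParams(rheobase_pA=145.0)
    for kind in ("short", "long"):
        ss, truth = synthetic.gen_step_protocol_traces(
            params, {"kind": kind}, seed=stage_seed(seed, f"fixtures:{kind}"))
        io.write_sweepset_csv(outdir / f"sweeps_{kind}.csv", ss, {
            **meta, "rheobase_on_grid_pA": truth["rheobase_on_grid_pA"],
            "v_threshold_mV": truth["v_threshold_mV"]})

    psc = synthetic.PSCModelParams(duration_s=10.0, sample_rate_Hz=10_000.0,
                                   rate_Hz=1.0)
    t, i_pA, events = synthetic.gen_psc_trace(
        psc, seed=stage_seed(seed, "fixtures:psc"))
    io.write_table_csv(outdir / "psc_trace.csv",
                       pd.DataFrame({"time_s": t, "current_pA": i_pA}), meta)
    io.write_table_csv(outdir / "psc_events.csv", events, meta)

    for preset in ("P15-Ctrl", "P15-Dep"):
        cohort = synthetic.gen_cohort(preset, n_animals=2, n_per_animal=100,
                                      seed=stage_seed(seed, f"fixtures:{preset}"))
        io.write_table_csv(outdir / f"cohort_{preset}.csv", cohort, meta)
    return outdir
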