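"""End-to-end pipeline driver: simulate -> LNO -> perf -> MVP -> equity.

A single structured config (YAML or dict) controls a reduced-scale run
of the whole framework on synthetic data. Every random stage has an
explicit seed; re-running with the same config reproduces identical
artifacts, and stages whose outputs already exist are skipped so that
deleting an intermediate recomputes only downstream stages. A manifest
(JSON) records resolved config, per-stage outputs with checksums, and
timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

from . import synthetic_data as sd
from . import allele_network
from .binding_data import write_binding_tsv
from .encoders import write_pseudosequences
from .equity_metrics import expected_group_value, write_frequency_tsv
from .lno_protocol import (
    load_campaign_manifest,
    run_lno_campaign,
    summary_from_records,
    write_campaign_manifest,
)
from .mvp_selector import select_mvp_alleles
from .panmhc import NetworkConfig
from .perf_estimator import PerfRegressor, featurize_experiments

logger = logging.getLogger(__name__)

STAGES = ("simulate", "network", "lno", "perf", "mvp", "equity")


@dataclass
class PipelineConfig:
    """Validated configuration for a reduced end-to-end run."""

    out_dir: str = "mhcequity_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # universe
    n_alleles: int = 60
    n_clusters: int = 5
    mutation_rate: float = 0.05
    n_data_alleles: int = 30
    noise_sd: float = 0.5
    ba_fraction: float = 0.2
    min_count: int = 50  # data-allele floor: campaign test alleles are data-rich
    # LNO campaign
    n_test_alleles: int = 15
    n_lno_sets: int = 4
    min_el: int = 50
    max_positives_per_allele: int | None = 150
    max_test_positives: int | None = 100
    member_hidden: int = 24
    member_epochs: int = 30
    member_patience: int = 6
    # MVP / equity
    n_mvp: int = 5
    n_added: int = 4000
    n_groups: int = 8
    concentration: float = 0.5

    def member_config(self) -> NetworkConfig:
        return NetworkConfig(
            hidden_units=(self.member_hidden,),
            skip_connections=(False,),
            learning_rate=3e-3,
            batch_size=1024,
            max_epochs=self.member_epochs,
            patience=self.member_patience,
            init_seed=self.seed,
        )


_FIELD_CHECKS = {
    "n_alleles": lambda v: v >= 1,
    "n_clusters": lambda v: v >= 1,
    "mutation_rate": lambda v: 0.0 <= v <= 1.0,
    "n_data_alleles": lambda v: v >= 1,
    "ba_fraction": lambda v: 0.0 <= v <= 1.0,
    "n_test_alleles": lambda v: v >= 2,
    "n_lno_sets": lambda v: v >= 1,
    "min_el": lambda v: v >= 1,
    "min_count": lambda v: v >= 1,
    "n_mvp": lambda v: v >= 1,
    "n_added": lambda v: v >= 1,
    "n_groups": lambda v: v >= 1,
    "concentration": lambda v: v > 0,
    "noise_sd": lambda v: v >= 0,
    "member_hidden": lambda v: v >= 1,
    "member_epochs": lambda v: v >= 1,
    "member_patience": lambda v: v >= 1,
}


def validate_config(raw: Mapping[str, Any]) -> PipelineConfig:
    """Build a typed config, reporting *all* violations at once."""
    known = set(PipelineConfig.__dataclass_fields__)
    violations = [f"unknown key: {k}" for k in raw if k not in known]
    merged = {**{k: v for k, v in raw.items() if k in known}}
    candidate = PipelineConfig(**merged)
    for name, check in _FIELD_CHECKS.items():
        v = getattr(candidate, name)
        try:
            ok = check(v)
        except TypeError:
            ok = False
        if not ok:
            violations.append(f"invalid value for {name}: {v!r}")
    if candidate.n_clusters > candidate.n_alleles:
        violations.append("n_clusters exceeds n_alleles")
    if candidate.n_data_alleles > candidate.n_alleles:
        violations.append("n_data_alleles exceeds n_alleles")
    for s in candidate.stages:
        if s not in STAGES:
            violations.append(f"unknown stage: {s}")
    if violations:
        raise ValueError("invalid config:\n  " + "\n  ".join(violations))
    return candidate


def load_config(path) -> PipelineConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return validate_config(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; return the manifest.

    Stage outputs land under ``config.out_dir``. A stage is skipped when
    all of its output files already exist, so deleting an intermediate
    and re-running recomputes only that stage and those after it (later
    stages always re-run when an upstream stage ran).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}
    upstream_ran = False

    def record(stage: str, files: list[Path], started: float, ran: bool) -> None:
        manifest["stages"][stage] = {
            "ran": ran,
            "seconds": round(time.time() - started, 3),
            "outputs": {f.name: _sha256(f) for f in files},
        }

    # ---- simulate -------------------------------------------------------
    pseudo_f = out / "pseudosequences.tsv"
    records_f = out / "binding_records.tsv"
    freq_f = out / "frequencies.tsv"
    stage_files = {
        "simulate": [pseudo_f, records_f, freq_f],
        "network": [out / "edges.tsv", out / "nodes.tsv"],
        "lno": [out / "lno_manifest.tsv"],
        "perf": [out / "perf_eval.json"],
        "mvp": [out / "mvp_selection.tsv"],
        "equity": [out / "equity_report.tsv"],
    }

    universe = sd.generate_allele_universe(
        config.n_alleles, config.n_clusters, config.mutation_rate, config.seed
    )
    oracle = sd.make_binding_oracle(universe, config.noise_sd, config.seed + 1)
    data_alleles = sd.allocate_data_alleles(universe, config.n_data_alleles)
    counts = sd.sample_power_law_counts(
        data_alleles, min_count=config.min_count, seed=config.seed + 2
    )
    proteome = sd.sample_proteome(seed=config.seed + 3)

    records = None
    freq = None
    if "simulate" in config.stages:
        t0 = time.time()
        if upstream_ran or not all(f.exists() for f in stage_files["simulate"]):
            records = sd.sample_binding_dataset(
                oracle, counts, config.ba_fraction, config.seed + 4
            )
            freq = sd.sample_population_frequencies(
                universe, config.n_groups, config.concentration, config.seed + 5
            )
            write_pseudosequences(universe.pseudosequences, pseudo_f)
            write_binding_tsv(records, records_f)
            write_frequency_tsv(freq, freq_f)
            upstream_ran = True
            record("simulate", stage_files["simulate"], t0, True)
        else:
            record("simulate", stage_files["simulate"], t0, False)

    def need(stage: str) -> bool:
        return upstream_ran or not all(f.exists() for f in stage_files[stage])

    def ensure_records():
        nonlocal records, freq
        if records is None:
            records = sd.sample_binding_dataset(
                oracle, counts, config.ba_fraction, config.seed + 4
            )
        if freq is None:
            freq = sd.sample_population_frequencies(
                universe, config.n_groups, config.concentration, config.seed + 5
            )

    # ---- network --------------------------------------------------------
    if "network" in config.stages:
        t0 = time.time()
        if need("network"):
            ensure_records()
            mass = {a: 0 for a in universe.alleles}
            for r in records:
                mass[r.allele] += 1
            # collapse identical pseudosequence strings to one node
            distinct: dict[str, str] = {}
            node_mass: dict[str, int] = {}
            for a in universe.alleles:
                ps = universe.pseudosequences[a]
                rep = distinct.setdefault(ps, a)
                node_mass[rep] = node_mass.get(rep, 0) + mass[a]
            nodes = {rep: ps for ps, rep in distinct.items()}
            g = allele_network.build_network(nodes, data_mass=node_mass)
            allele_network.write_edge_list(g, out / "edges.tsv")
            allele_network.write_node_table(g, out / "nodes.tsv")
            upstream_ran = True
            record("network", stage_files["network"], t0, True)
        else:
            record("network", stage_files["network"], t0, False)

    # ---- lno ------------------------------------------------------------
    experiments = None
    if "lno" in config.stages:
        t0 = time.time()
        if need("lno"):
            ensure_records()
            experiments = run_lno_campaign(
                records,
                universe.pseudosequences,
                proteome,
                config.member_config(),
                n_test_alleles=config.n_test_alleles,
                n_sets=config.n_lno_sets,
                min_el=config.min_el,
                max_positives_per_allele=config.max_positives_per_allele,
                max_test_positives=config.max_test_positives,
                seed=config.seed + 6,
                progress=logger.info,
            )
            write_campaign_manifest(experiments, out / "lno_manifest.tsv")
            upstream_ran = True
            record("lno", stage_files["lno"], t0, True)
        else:
            record("lno", stage_files["lno"], t0, False)

    # ---- perf -----------------------------------------------------------
    perf_model = None
    if "perf" in config.stages:
        t0 = time.time()
        if need("perf"):
            if experiments is None:
                if not (out / "lno_manifest.tsv").exists():
                    raise RuntimeError("perf stage requires the lno stage output")
                ensure_records()
                experiments = load_campaign_manifest(
                    out / "lno_manifest.tsv", records, universe.pseudosequences
                )
            X, y = featurize_experiments(experiments, universe.pseudosequences)
            perf_model = PerfRegressor(seed=config.seed + 7).fit(X, y)
            (out / "perf_eval.json").write_text(
                json.dumps(
                    {
                        "n_experiments": len(experiments),
                        "train_val_loss": perf_model.best_val_loss_,
                        "epochs": perf_model.n_epochs_,
                    },
                    indent=2,
                )
            )
            upstream_ran = True
            record("perf", stage_files["perf"], t0, True)
        else:
            record("perf", stage_files["perf"], t0, False)

    def ensure_perf_model():
        nonlocal perf_model, experiments
        if perf_model is None:
            if experiments is None:
                if not (out / "lno_manifest.tsv").exists():
                    raise RuntimeError("this stage requires the lno stage output")
                ensure_records()
                experiments = load_campaign_manifest(
                    out / "lno_manifest.tsv", records, universe.pseudosequences
                )
            X, y = featurize_experiments(experiments, universe.pseudosequences)
            perf_model = PerfRegressor(seed=config.seed + 7).fit(X, y)

    # ---- mvp ------------------------------------------------------------
    mvp = None
    if "mvp" in config.stages:
        t0 = time.time()
        if need("mvp"):
            ensure_perf_model()
            ensure_records()
            summary = summary_from_records(records, universe.pseudosequences)
            # the selector needs pseudosequences for no-data alleles too
            summary = type(summary)(
                counts={a: summary.counts.get(a, 0) for a in universe.alleles},
                pseudosequences=dict(universe.pseudosequences),
            )
            mvp = select_mvp_alleles(
                perf_model, universe.pseudosequences, summary,
                k=config.n_mvp, n_added=config.n_added,
            )
            lines = ["rank\tallele\tscore"]
            for i, (a, s) in enumerate(zip(mvp.selected, mvp.scores), 1):
                lines.append(f"{i}\t{a}\t{s:.6f}")
            (out / "mvp_selection.tsv").write_text("\n".join(lines) + "\n")
            upstream_ran = True
            record("mvp", stage_files["mvp"], t0, True)
        else:
            record("mvp", stage_files["mvp"], t0, False)

    # ---- equity ---------------------------------------------------------
    if "equity" in config.stages:
        t0 = time.time()
        if need("equity"):
            if mvp is None:
                ensure_perf_model()
                ensure_records()
                summary = summary_from_records(records, universe.pseudosequences)
                summary = type(summary)(
                    counts={a: summary.counts.get(a, 0) for a in universe.alleles},
                    pseudosequences=dict(universe.pseudosequences),
                )
                mvp = select_mvp_alleles(
                    perf_model, universe.pseudosequences, summary,
                    k=config.n_mvp, n_added=config.n_added,
                )
            ensure_records()
            rows = ["group\texpected_ppv_before\texpected_ppv_after"]
            groups = sorted(freq["group"].unique())
            for gname in groups:
                before = expected_group_value(mvp.ppv_before, freq, gname)
                after = expected_group_value(mvp.ppv_after, freq, gname)
                rows.append(f"{gname}\t{before:.4f}\t{after:.4f}")
            (out / "equity_report.tsv").write_text("\n".join(rows) + "\n")
            upstream_ran = True
            record("equity", stage_files["equity"], t0, True)
        else:
            record("equity", stage_files["equity"], t0, False)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def run_reduced_study(seed: int = 1, config: PipelineConfig | None = None) -> dict:
    """The desk-scale end-to-end study, entirely in memory.

    Generates the synthetic universe (60 alleles, 5 clusters, 30 with
    data under a cluster-skewed power law), runs the reduced LNO
    campaign (15 test alleles x 4 sets, one small member per training
    set), cross-validates the performance estimator against the
    nearest-neighbor baseline with PPV-balanced folds, trains the final
    estimator on all experiments, and runs the greedy MVP selection with
    4,000 hypothetical records per pick. Returns every intermediate the
    analysis needs.
    """
    import numpy as np

    from .mvp_selector import select_mvp_alleles
    from .perf_estimator import cross_validated_evaluation
    from .lno_protocol import TrainingDataSummary

    cfg = config or PipelineConfig(seed=seed)
    universe = sd.generate_allele_universe(
        cfg.n_alleles, cfg.n_clusters, cfg.mutation_rate, seed
    )
    oracle = sd.make_binding_oracle(universe, cfg.noise_sd, seed + 1)
    data_alleles = sd.allocate_data_alleles(universe, cfg.n_data_alleles)
    counts = sd.sample_power_law_counts(
        data_alleles, min_count=cfg.min_count, seed=seed + 2
    )
    records = sd.sample_binding_dataset(oracle, counts, cfg.ba_fraction, seed + 4)
    proteome = sd.sample_proteome(seed=seed + 3)
    experiments = run_lno_campaign(
        records,
        universe.pseudosequences,
        proteome,
        cfg.member_config(),
        n_test_alleles=cfg.n_test_alleles,
        n_sets=cfg.n_lno_sets,
        min_el=cfg.min_el,
        max_positives_per_allele=cfg.max_positives_per_allele,
        max_test_positives=cfg.max_test_positives,
        seed=seed + 6,
        progress=logger.info,
    )
    evaluation = cross_validated_evaluation(
        experiments, universe.pseudosequences, k=5, seed=seed + 7
    )
    X, y = featurize_experiments(experiments, universe.pseudosequences)
    final_model = PerfRegressor(seed=seed + 8).fit(X, y)
    full_summary = TrainingDataSummary(
        counts={a: counts.get(a, 0) for a in universe.alleles},
        pseudosequences=dict(universe.pseudosequences),
    )
    mvp = select_mvp_alleles(
        final_model, universe.pseudosequences, full_summary,
        k=cfg.n_mvp, n_added=cfg.n_added,
    )
    before = np.array([mvp.ppv_before[a] for a in universe.alleles])
    after = np.array([mvp.ppv_after[a] for a in universe.alleles])
    return {
        "universe": universe,
        "oracle": oracle,
        "counts": counts,
        "records": records,
        "proteome": proteome,
        "experiments": experiments,
        "evaluation": evaluation,
        "final_model": final_model,
        "mvp": mvp,
        "ppv_sd_before": float(before.std()),
        "ppv_sd_after": float(after.std()),
        "ppv_mean_before": float(before.mean()),
        "ppv_mean_after": float(after.mean()),
    }
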