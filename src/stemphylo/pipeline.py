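"""End-to-end orchestration: variants -> MP + BI -> diagnostics -> tables.

A single structured config drives the whole analysis grid: a base matrix
(file or synthetic), a list of recoding plans, parsimony and MCMC settings,
and clade definitions.  Every stage writes plain-text outputs (NEXUS,
newick, TSV, JSON) into the output directory, logs its seed, and leaves a
completion marker keyed by a config hash so reruns skip finished stages
without changing results.

Two scales are supported: ``desk`` (default; minutes on one CPU) and
``paper`` (the study geometry: 4 runs x 4 chains, >= 20M generations).
Convergence thresholds (ASDSF < 0.01, ESS > 200) are enforced as pass/fail
only at paper scale and reported informatively at desk scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import hypothesis, mk_mcmc, parsimony, recode, synthdata, treespace
from .hypothesis import CladeDefinitions
from .mk_mcmc import MkModelConfig, PosteriorSample, RunSettings, strategy_preset
from .nexus_io import (
    CharacterMatrix,
    Provenance,
    TreeRecord,
    parse_matrix,
    parse_trees,
    serialize_matrix,
    serialize_trees,
)
from .parsimony import SearchSettings
from .recode import RecodingPlan

__all__ = ["AnalysisConfig", "VariantSpec", "RunReport", "run_analysis", "stage_seed"]

log = logging.getLogger("stemphylo")

ASDSF_THRESHOLD = 0.01
ESS_THRESHOLD = 200.0


def stage_seed(master_seed: int, label: str, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    h = zlib.crc32(f"{label}:{stage}".encode())
    return (master_seed * 1_000_003 + h) % (2**31 - 1)


@dataclass
class VariantSpec:
    label: str
    plan: RecodingPlan = field(default_factory=RecodingPlan)
    expected_dims: tuple[int, int] | None = None


@dataclass
class AnalysisConfig:
    base_matrix: str = "synthetic"  # path or the literal 'synthetic'
    output_dir: str = "stemphylo_out"
    master_seed: int = 1
    scale: str = "desk"  # desk | paper
    synthetic: dict = field(default_factory=dict)  # SimConfig overrides
    variants: list[VariantSpec] = field(default_factory=list)
    mp: dict = field(default_factory=dict)  # SearchSettings overrides
    bi: dict = field(default_factory=dict)  # MkModelConfig/RunSettings overrides
    strategy: str = "maximise_information"
    run_mp: bool = True
    run_bi: bool = True

    def __post_init__(self) -> None:
        labels = [v.label for v in self.variants]
        if len(set(labels)) != len(labels):
            raise ValueError("variant labels must be unique")
        if self.scale not in ("desk", "paper"):
            raise ValueError("scale must be 'desk' or 'paper'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        variants = []
        for v in raw.pop("variants", []):
            plan = RecodingPlan(
                merge=tuple(v["merge"]) if v.get("merge") else None,
                add_taxa=[
                    recode.AddedTaxon.from_string(a["name"], a["scoring"],
                                                  variant_label=a.get("variant_label", ""),
                                                  groups=tuple(a.get("groups", ())))
                    for a in v.get("add_taxa", [])
                ],
                convergent_features=tuple(v.get("convergent_features", ())),
                feature_actions={
                    f: recode.FeatureAction(**a)
                    for f, a in v.get("feature_actions", {}).items()
                },
            )
            variants.append(
                VariantSpec(
                    label=v["label"],
                    plan=plan,
                    expected_dims=tuple(v["expected_dims"]) if v.get("expected_dims") else None,
                )
            )
        return cls(variants=variants, **raw)

    def config_hash(self) -> str:
        payload = json.dumps(_to_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(x) for x in obj]
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    return obj


@dataclass
class RunReport:
    config_hash: str
    stages: dict[str, dict] = field(default_factory=dict)
    summary: pd.DataFrame | None = None

    def record(self, name: str, status: str, seconds: float, **info) -> None:
        self.stages[name] = {"status": status, "seconds": round(seconds, 3), **info}

    def to_json(self) -> str:
        payload = {
            "config_hash": self.config_hash,
            "stages": self.stages,
        }
        if self.summary is not None:
            payload["summary"] = self.summary.to_dict(orient="records")
        return json.dumps(payload, indent=2, default=str)


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------


def _marker(out: Path, name: str) -> Path:
    return out / f"{name}.done"


def _stage_complete(out: Path, name: str, cfg_hash: str) -> bool:
    mk = _marker(out, name)
    return mk.exists() and mk.read_text().strip() == cfg_hash


def _finish_stage(out: Path, name: str, cfg_hash: str) -> None:
    _marker(out, name).write_text(cfg_hash + "\n")


def _base_matrix(cfg: AnalysisConfig) -> CharacterMatrix:
    if cfg.base_matrix == "synthetic":
        overrides = dict(cfg.synthetic)
        overrides.setdefault("seed", stage_seed(cfg.master_seed, "base", "simulate"))
        sim = synthdata.SimConfig(**overrides)
        rec = synthdata.simulate_yule_tree(
            sim.n_taxa, sim.birth_rate,
            constraints=sim.group_template, seed=sim.seed,
        )
        m = synthdata.simulate_characters(
            rec, sim.n_chars, sim.state_count_distribution, sim.char_rate, seed=sim.seed
        )
        template = sim.group_template
        deut = template.get("deuteropods", [])
        og = template.get("outgroup", [])
        extant = (deut[: sim.n_extant] + og)[: sim.n_extant]
        m.taxon_flags = {t: ("extant" if t in extant else "fossil") for t in m.taxon_names}
        m.group_map = {g: frozenset(v) for g, v in template.items()}
        return synthdata.apply_missingness(
            m, m.fossil_taxa(), sim.missing_fraction_fossil,
            sim.missing_fraction_extant, seed=sim.seed,
        )
    return parse_matrix(Path(cfg.base_matrix).read_text())


def _search_settings(cfg: AnalysisConfig, label: str) -> SearchSettings:
    opts = dict(cfg.mp)
    if cfg.scale == "paper":
        opts.setdefault("required_hits", 100)
        opts.setdefault("n_random_addition_starts", 1000)
    else:
        opts.setdefault("required_hits", 5)
        opts.setdefault("n_random_addition_starts", 25)
    opts.setdefault("concavity_k", 3.0)
    opts["seed"] = stage_seed(cfg.master_seed, label, "mp")
    return SearchSettings(**opts)


def _bi_settings(cfg: AnalysisConfig, label: str) -> tuple[MkModelConfig, RunSettings]:
    opts = dict(cfg.bi)
    run_fields = {f.name for f in dataclasses.fields(RunSettings)}
    run_opts = {k: v for k, v in opts.items() if k in run_fields}
    model_opts = {k: v for k, v in opts.items() if k not in run_fields}
    rs = RunSettings.paper_scale() if cfg.scale == "paper" else RunSettings.desk_scale()
    for k, v in run_opts.items():
        setattr(rs, k, v)
    mcfg = strategy_preset(cfg.strategy, **model_opts)
    mcfg.seed = stage_seed(cfg.master_seed, label, "bi")
    return mcfg, rs


def _write_bi_outputs(out: Path, label: str, sample: PosteriorSample) -> None:
    by_run = sample.trees_by_run()
    for r, trees in enumerate(by_run):
        (out / f"{label}.bi_trees_run{r}.nwk").write_text(serialize_trees(trees))
        df = pd.DataFrame({"lnL": sample.lnL_trace[r]})
        for name, per_run in sample.parameter_traces.items():
            df[name] = per_run[r]
        df.insert(0, "generation", [t.provenance.index for t in trees])
        df.to_csv(out / f"{label}.bi_trace_run{r}.tsv", sep="\t", index=False)


def _load_bi_outputs(out: Path, label: str, n_runs: int) -> PosteriorSample:
    trees: list[TreeRecord] = []
    lnL: list[np.ndarray] = []
    params: dict[str, list[np.ndarray]] = {}
    for r in range(n_runs):
        recs = parse_trees((out / f"{label}.bi_trees_run{r}.nwk").read_text(), analysis="bi")
        df = pd.read_csv(out / f"{label}.bi_trace_run{r}.tsv", sep="\t")
        for i, rec in enumerate(recs):
            gen = int(df["generation"].iloc[i]) if "generation" in df else i
            trees.append(TreeRecord(rec.tree, Provenance("bi", run=r, index=gen)))
        lnL.append(df["lnL"].to_numpy())
        for col in df.columns:
            if col in ("generation", "lnL"):
                continue
            params.setdefault(col, []).append(df[col].to_numpy())
    return PosteriorSample(trees=trees, lnL_trace=lnL, parameter_traces=params,
                           burnin_applied=True, n_runs=n_runs)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def run_analysis(cfg: AnalysisConfig) -> RunReport:
    """Run the full grid; returns the report (also written to report.json)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    (out / "config.yaml").write_text(yaml.safe_dump(_to_jsonable(cfg), sort_keys=False))
    report = RunReport(config_hash=cfg_hash)

    t0 = time.time()
    base = _base_matrix(cfg)
    (out / "base_matrix.nex").write_text(serialize_matrix(base))
    report.record("base_matrix", "ok", time.time() - t0,
                  ntax=base.ntax, nchar=base.nchar)

    variants = cfg.variants or [VariantSpec(label="base")]
    summary_rows = []
    bi_samples: dict[str, PosteriorSample] = {}

    for vs in variants:
        name = vs.label
        t0 = time.time()
        try:
            variant = recode.build_matrix_variant(base, vs.plan, name,
                                                  expected_dims=vs.expected_dims)
        except Exception as exc:  # noqa: BLE001 - report and skip dependants
            report.record(f"{name}.recode", "failed", time.time() - t0, error=str(exc))
            log.error("variant %s failed to build: %s", name, exc)
            continue
        m = variant.matrix
        (out / f"{name}.nex").write_text(serialize_matrix(m))
        report.record(f"{name}.recode", "ok", time.time() - t0,
                      ntax=m.ntax, nchar=m.nchar)

        try:
            defs = CladeDefinitions.from_matrix(m)
        except ValueError:
            defs = None

        mp_trees: list[TreeRecord] = []
        if cfg.run_mp:
            t0 = time.time()
            stage = f"{name}.mp"
            if _stage_complete(out, stage, cfg_hash):
                mp_trees = parse_trees((out / f"{name}.mp_trees.nwk").read_text(), "mp")
                report.record(stage, "skipped", 0.0)
            else:
                try:
                    ss = _search_settings(cfg, name)
                    result = parsimony.search_mp(m, ss)
                    mp_trees = result.trees
                    (out / f"{name}.mp_trees.nwk").write_text(serialize_trees(mp_trees))
                    cons = parsimony.strict_consensus(mp_trees)
                    (out / f"{name}.mp_strict_consensus.nwk").write_text(
                        serialize_trees([cons])
                    )
                    fit = result.best_score
                    pd.DataFrame({
                        "character": np.arange(1, m.nchar + 1),
                        "steps": fit.per_char_steps,
                        "min_steps": fit.per_char_min,
                        "extra_steps": fit.per_char_extra,
                        "fit": fit.concavity_k / (fit.concavity_k + fit.per_char_extra),
                    }).to_csv(out / f"{name}.mp_fit.tsv", sep="\t", index=False)
                    _finish_stage(out, stage, cfg_hash)
                    report.record(stage, "ok", time.time() - t0,
                                  n_trees=len(mp_trees), seed=ss.seed,
                                  fit_total=fit.fit_total, hits=result.hits,
                                  budget_exhausted=result.budget_exhausted)
                except Exception as exc:  # noqa: BLE001
                    report.record(stage, "failed", time.time() - t0, error=str(exc))
                    log.error("MP stage for %s failed: %s", name, exc)

        sample: PosteriorSample | None = None
        if cfg.run_bi:
            t0 = time.time()
            stage = f"{name}.bi"
            mcfg, rs = _bi_settings(cfg, name)
            if _stage_complete(out, stage, cfg_hash):
                sample = _load_bi_outputs(out, name, rs.n_runs)
                report.record(stage, "skipped", 0.0)
            else:
                try:
                    sample = mk_mcmc.run_mcmc(m, mcfg, rs)
                    _write_bi_outputs(out, name, sample)
                    _finish_stage(out, stage, cfg_hash)
                    report.record(stage, "ok", time.time() - t0,
                                  seed=mcfg.seed, n_trees=len(sample.trees),
                                  n_generations=rs.n_generations)
                except Exception as exc:  # noqa: BLE001
                    report.record(stage, "failed", time.time() - t0, error=str(exc))
                    log.error("BI stage for %s failed: %s", name, exc)

            if sample is not None:
                t0 = time.time()
                diag: dict[str, Any] = {}
                try:
                    diag["asdsf"] = mk_mcmc.compute_asdsf(sample)
                except ValueError:
                    diag["asdsf"] = None
                ess: dict[str, float] = {}
                for pname, per_run in sample.parameter_traces.items():
                    pooled = np.concatenate(per_run)
                    if len(pooled) >= 10:
                        ess[pname] = mk_mcmc.compute_ess(pooled)
                lnl_pooled = np.concatenate(sample.lnL_trace)
                if len(lnl_pooled) >= 10:
                    ess["lnL"] = mk_mcmc.compute_ess(lnl_pooled)
                diag["ess"] = ess
                if cfg.scale == "paper":
                    ok = (diag["asdsf"] is not None and diag["asdsf"] < ASDSF_THRESHOLD
                          and all(v > ESS_THRESHOLD for v in ess.values()))
                    diag["converged"] = bool(ok)
                (out / f"{name}.diagnostics.json").write_text(
                    json.dumps(diag, indent=2, default=float)
                )
                report.record(f"{name}.diagnose", "ok", time.time() - t0, **{
                    "asdsf": diag["asdsf"],
                    "min_ess": min(ess.values()) if ess else None,
                })
                cons = mk_mcmc.majority_consensus(sample)
                (out / f"{name}.bi_majority_consensus.nwk").write_text(
                    serialize_trees([cons])
                )
                bi_samples[name] = sample

        if defs is not None:
            t0 = time.time()
            try:
                samples_for_tab: dict[str, list[TreeRecord]] = {}
                if sample is not None:
                    samples_for_tab[f"{name}.bi"] = sample.trees
                if mp_trees:
                    samples_for_tab[f"{name}.mp"] = mp_trees
                if samples_for_tab:
                    table = hypothesis.tabulate_proportions(samples_for_tab, defs)
                    table.to_tsv(out / f"{name}.classification.tsv")
                    cats = hypothesis.classify_sample(
                        sample.trees if sample is not None else mp_trees, defs
                    )
                    pd.DataFrame({
                        "tree_index": np.arange(len(cats)),
                        "category": [c.category for c in cats],
                        "subcategory": [c.subcategory for c in cats],
                    }).to_csv(out / f"{name}.tree_categories.tsv", sep="\t", index=False)
                    for _, row in table.table.iterrows():
                        summary_rows.append(dict(row))
                    report.record(f"{name}.classify", "ok", time.time() - t0)
            except Exception as exc:  # noqa: BLE001
                report.record(f"{name}.classify", "failed", time.time() - t0,
                              error=str(exc))
        else:
            report.record(f"{name}.classify", "skipped", 0.0,
                          reason="matrix lacks hypothesis groups")

        if defs is not None and sample is not None:
            t0 = time.time()
            try:
                sub = sample.trees
                d = treespace.pairwise_distances(sub)
                emb = treespace.classical_mds(d, n_axes=min(3, max(1, d.n - 1)))
                emb.to_frame().to_csv(out / f"{name}.mds_coordinates.tsv",
                                      sep="\t", index=False)
                cats = hypothesis.classify_sample(sub, defs)
                groups = {i: c.category for i, c in enumerate(cats)}
                if len(set(groups.values())) >= 2:
                    rep = treespace.overlap_summary(emb, groups)
                    rep.to_frame().to_csv(out / f"{name}.mds_overlap.tsv",
                                          sep="\t", index=False)
                report.record(f"{name}.treespace", "ok", time.time() - t0,
                              n_trees=len(sub))
            except Exception as exc:  # noqa: BLE001
                report.record(f"{name}.treespace", "failed", time.time() - t0,
                              error=str(exc))

    if summary_rows:
        report.summary = pd.DataFrame(summary_rows)
        report.summary.to_csv(out / "summary_classification.tsv", sep="\t", index=False)
    (out / "report.json").write_text(report.to_json())
    return report
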