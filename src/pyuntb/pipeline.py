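"""Run every neutrality analysis over a multi-treatment OTU-table collection.

Each treatment (a labeled OTU table) is analyzed independently: per-sample
Hubbell neutrality tests with the treatment passing rate and a P-threshold
sweep, the stochasticity ratio, and the multi-site HDP fit with its
metacommunity/local tests; each ordered treatment pair gets a Sloan
source/destination fit (optionally the same-set scheme); each sample
optionally gets the IF/PC power analysis.  All randomness flows from the
single configured seed through named substreams, so a rerun with the same
configuration reproduces the report byte for byte.  A failing stage is
logged and marked failed in the report; the pipeline continues.

No rarefaction is performed anywhere; reports carry raw-count analyses
after the minimum-read filter only.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, hnm, msn, nsr, power, sloan
from .community import logger

SCHEMA_VERSION = "1.0"

_DEFAULTS = dict(
    min_reads=100, apply_min_reads_filter=True, alpha=0.05,
    n_sim=500, thresholds=[0.05, 0.1, 0.2, 0.3, 0.4, 0.5],
    n_null=1000, null_algorithm="proportional_frequency",
    n_gibbs=5000, burn_in=2500, msn_n_sim=500,
    sloan_same_set=False, sloan_pairs=None, detection_threshold=None,
    run_pnt=False, pnt_models=["IF", "PC"], pnt_effects=[0.5, 2.0],
    pnt_n_datasets=50, pnt_n_sim=200,
    seed=0,
)


@dataclass
class PipelineConfig:
    """Treatment table paths plus per-analysis parameters (missing entries
    fall back to documented defaults)."""

    treatments: dict
    output_dir: str = "pyuntb_out"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.params) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        merged = dict(_DEFAULTS)
        merged.update(self.params)
        self.params = merged

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls(treatments=raw["treatments"],
                   output_dir=raw.get("output_dir", "pyuntb_out"),
                   params=raw.get("params", {}))


def _seed_for(base: int, *names) -> np.random.SeedSequence:
    # named substreams; crc32 is stable across processes (unlike hash())
    key = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.SeedSequence(entropy=base, spawn_key=tuple(key))


def _load_treatment(label, source, p):
    cm = source if isinstance(source, community.CommunityMatrix) \
        else community.read_otu_table(source)
    if p["apply_min_reads_filter"]:
        cm = community.filter_min_reads(cm, p["min_reads"])
    return cm


def _stage_hnm(label, cm, p):
    rows = []
    for sid in cm.sample_ids:
        sad = community.extract_sad(cm, sid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = hnm.hnm_neutrality_test(
                sad, n_sim=p["n_sim"], alpha=p["alpha"],
                seed=_seed_for(p["seed"], "hnm", label, sid))
        rows.append({"treatment": label, "sample": sid, **res.to_dict()})
    pvals = [r["pseudo_p"] for r in rows]
    curve = hnm.passing_rate_curve(pvals, p["thresholds"])
    return {"samples": rows,
            "passing_rate": float(np.mean([pv > p["alpha"] for pv in pvals])),
            "threshold_sweep": dict(zip(map(str, p["thresholds"]),
                                        curve.tolist()))}


def _stage_nsr(label, cm, p):
    res = nsr.compute_stochasticity(
        cm, n_null=p["n_null"], null_algorithm=p["null_algorithm"],
        seed=_seed_for(p["seed"], "nsr", label))
    return res.to_dict()


def _stage_msn(label, cm, p):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = msn.fit_msn(cm, n_gibbs=p["n_gibbs"], burn_in=p["burn_in"],
                          seed=_seed_for(p["seed"], "msn_fit", label))
        test = msn.msn_neutrality_test(
            fit, cm, n_sim=p["msn_n_sim"],
            seed=_seed_for(p["seed"], "msn_test", label))
    out = fit.to_dict()
    out.update(test.to_dict())
    out["pass_metacommunity"] = test.P_M > p["alpha"]
    out["pass_local"] = [float(x) > p["alpha"] for x in test.P_L]
    return out


def _stage_sloan(src_label, src_cm, dst_label, dst_cm, p):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit, cls = sloan.fit_sloan(
            src_cm, dst_cm, detection_threshold=p["detection_threshold"])
    return {"source": src_label, "destination": dst_label,
            **fit.to_dict(), **cls.to_dict()}


def _stage_pnt(label, cm, p):
    rows = []
    for sid in cm.sample_ids:
        sad = community.extract_sad(cm, sid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obs = hnm.hnm_neutrality_test(
                sad, n_sim=p["pnt_n_sim"], alpha=p["alpha"],
                seed=_seed_for(p["seed"], "pnt_obs", label, sid))
            for model in p["pnt_models"]:
                for effect in p["pnt_effects"]:
                    pr = power.run_power_analysis(
                        obs.fit, model, effect,
                        n_datasets=p["pnt_n_datasets"],
                        n_sim_per_test=p["pnt_n_sim"], alpha=p["alpha"],
                        seed=_seed_for(p["seed"], "pnt", label, sid,
                                       model, str(effect)))
                    det = power.detect_non_neutral(obs.pseudo_p, pr.ave_p)
                    fn = power.classify_false_negative(obs.pseudo_p,
                                                       pr.ave_p, p["alpha"])
                    rows.append({"treatment": label, "sample": sid,
                                 "p_observed": obs.pseudo_p,
                                 **pr.to_dict(),
                                 "non_neutral_detected": det,
                                 "false_negative": fn})
    verdicts = [power.DetectionVerdict(r["p_observed"], r["ave_p"],
                                       r["non_neutral_detected"],
                                       r["false_negative"], p["alpha"])
                for r in rows]
    return {"samples": rows, "summary": power.summarize_pnt(verdicts)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the consolidated report."""
    p = config.params
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = {"schema_version": SCHEMA_VERSION, "params": dict(p),
              "treatments": {}, "sloan_pairs": [], "skipped": []}

    tables = {}
    for label, source in config.treatments.items():
        try:
            tables[label] = _load_treatment(label, source, p)
        except Exception as exc:  # isolate per-treatment failures
            logger.error("treatment %s skipped: %s", label, exc)
            report["skipped"].append({"treatment": label, "reason": str(exc)})

    for label, cm in tables.items():
        block = {"n_samples": cm.n_samples, "n_otus": cm.n_otus,
                 "dropped_samples": cm.dropped_samples}
        stages = [("hnm", _stage_hnm), ("nsr", _stage_nsr),
                  ("msn", _stage_msn)]
        if p["run_pnt"]:
            stages.append(("pnt", _stage_pnt))
        for name, fn in stages:
            try:
                block[name] = fn(label, cm, p)
            except Exception as exc:
                logger.error("stage %s failed for %s: %s", name, label, exc)
                block[name] = {"failed": True, "reason": str(exc)}
        report["treatments"][label] = block

    labels = list(tables)
    if p["sloan_pairs"]:
        pairs = [tuple(pr) for pr in p["sloan_pairs"]]
    elif p["sloan_same_set"]:
        pairs = [(lb, lb) for lb in labels]
    else:
        pairs = [(a, b) for a in labels for b in labels if a != b]
    for src, dst in pairs:
        if src not in tables or dst not in tables:
            continue
        try:
            report["sloan_pairs"].append(
                _stage_sloan(src, tables[src], dst, tables[dst], p))
        except Exception as exc:
            logger.error("sloan %s->%s failed: %s", src, dst, exc)
            report["sloan_pairs"].append(
                {"source": src, "destination": dst,
                 "failed": True, "reason": str(exc)})

    _write_outputs(report, out_dir)
    return report


def _write_outputs(report: dict, out_dir: Path) -> None:
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    hnm_rows, nsr_rows, msn_rows, pnt_rows = [], [], [], []
    for label, block in report["treatments"].items():
        if isinstance(block.get("hnm"), dict) and "samples" in block["hnm"]:
            hnm_rows += block["hnm"]["samples"]
        if isinstance(block.get("nsr"), dict) and "SR" in block.get("nsr", {}):
            nsr_rows.append({"treatment": label, **block["nsr"]})
        m = block.get("msn", {})
        if isinstance(m, dict) and "theta" in m:
            msn_rows.append({"treatment": label, "theta": m["theta"],
                             "P_M": m["P_M"],
                             "mean_P_L": float(np.mean(m["P_L"]))})
        if isinstance(block.get("pnt"), dict) and "samples" in block.get("pnt", {}):
            pnt_rows += block["pnt"]["samples"]
    for name, rows in (("hnm", hnm_rows), ("nsr", nsr_rows),
                       ("msn", msn_rows), ("sloan", report["sloan_pairs"]),
                       ("pnt", pnt_rows)):
        if rows:
            pd.DataFrame(rows).to_csv(out_dir / f"{name}.tsv",
                                      sep="\t", index=False)
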