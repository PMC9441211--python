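"""End-to-end orchestration: simulate -> parse -> classify -> profile ->
analyze, with a run manifest for reproducibility accounting.

Every stage writes CSV artifacts; the manifest (JSON, written last) records
the configuration hash, seed, per-stage record counts, stage timings and
output checksums.  Counts conserve across stages: read = parsed +
parse_failures, and every parsed case is classified.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import analytics, attribution, classify, report_io, simulate
from .config import CohortConfig
from .lexicon import TissueDictionary, default_dictionary
from .types import ClassifiedCase, ParseFailure

log = logging.getLogger("pathreq_audit")

__all__ = ["RunManifest", "run_pipeline", "analyze_cases"]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    counts: dict[str, int] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Timer:
    def __init__(self, manifest: RunManifest, stage: str) -> None:
        self.manifest, self.stage = manifest, stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.manifest.timings_s[self.stage] = round(
            time.perf_counter() - self.t0, 3)
        return False


def _failures_frame(failures: Sequence[ParseFailure]) -> pd.DataFrame:
    return pd.DataFrame(
        [[f.case_id, f.reason] for f in failures],
        columns=["case_id", "reason"],
    )


def analyze_cases(cases: Sequence[ClassifiedCase],
                  out_dir: str | Path, min_cases: int = 200,
                  bins: int = 20) -> dict[str, Path]:
    """Write the full set of result tables for a classified cohort.

    Emits the year, site-by-year, tissue-group (with whole-cohort total
    row) and intent rate tables, the SPS profile table and summary, the
    univariate regression table, and the provider-rate histogram/density
    tables.  Returns the mapping of artifact name to path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = analytics.cases_to_frame(cases)
    outputs: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / f"{name}.csv"
        report_io.write_table(frame, path)
        outputs[name] = path

    emit("rates_by_year",
         analytics.present_rate_table(analytics.rate_table(df, ["year"])))
    emit("rates_by_site_year",
         analytics.present_rate_table(
             analytics.rate_table(df, ["site", "year"])))
    tg = analytics.rate_table(df, ["tissue_group"]).sort_values(
        "volume", ascending=False)
    total = pd.DataFrame({
        "tissue_group": ["Whole cohort"],
        "volume": [int(tg["volume"].sum())],
        "chp": [int(tg["chp"].sum())],
        "rate": [tg["chp"].sum() / tg["volume"].sum() if len(tg) else 0.0],
        "fraction_of_total": [1.0],
    })
    emit("rates_by_tissue_group",
         analytics.present_rate_table(
             pd.concat([tg, total], ignore_index=True) if len(tg) else tg))
    emit("rates_by_intent",
         analytics.present_rate_table(analytics.rate_table(df, ["intent"])))

    profiles = attribution.sps_profiles(cases, min_cases=min_cases)
    emit("sps_profiles", pd.DataFrame(
        [[p.sps_code, p.assigned_site, p.n_cases, p.n_chp, p.chp_rate]
         for p in profiles],
        columns=["sps_code", "assigned_site", "n_cases", "n_chp", "chp_rate"],
    ))
    if profiles:
        summary = attribution.profile_summary(profiles)
        emit("sps_summary", pd.DataFrame(
            [[v, *summary[v].values()] for v in summary],
            columns=["variable", "mean", "median", "sd", "max", "min"],
        ))
        dist = analytics.distribution_summary(profiles, bins=bins)
        emit("histogram", pd.DataFrame({
            "bin_left": dist.bin_edges[:-1], "bin_right": dist.bin_edges[1:],
            "count": dist.counts,
        }))
        emit("density", pd.DataFrame({
            "rate": dist.grid, "density": dist.density}))
        if len(profiles) >= 3:
            rho, p = analytics.volume_association(profiles)
            emit("volume_association", pd.DataFrame(
                {"statistic": ["spearman_rho"], "value": [rho],
                 "p_value": [p]}))

    reg_rows = []
    for predictor in ("workload_units", "blocks", "intent", "tissue_group",
                      "year", "site"):
        if predictor in df.columns and df[predictor].nunique() >= 2:
            r = analytics.fit_univariate_logistic(df, predictor)
            reg_rows.append([r.predictor, r.coding, r.n, r.lrt_statistic,
                             r.p_value, r.converged, r.separation])
    if reg_rows:
        emit("regressions", pd.DataFrame(
            reg_rows, columns=["predictor", "coding", "n", "lrt_statistic",
                               "p_value", "converged", "separation"]))
    return outputs


def run_pipeline(config: CohortConfig, out_dir: str | Path,
                 dictionary: TissueDictionary | None = None,
                 min_cases: int = 200,
                 strict: bool = False) -> RunManifest:
    """Run the full pipeline on a synthetic cohort and write all artifacts.

    Reruns with the same configuration produce byte-identical CSV
    contents.  With ``strict=True`` any record-level parse failure is
    fatal.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dictionary = dictionary or default_dictionary()
    config_bytes = config.model_dump_json().encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_bytes).hexdigest(),
        seed=config.seed,
    )

    with _Timer(manifest, "simulate"):
        reports, truths = simulate.generate_corpus(config)
        corpus_path = out_dir / "corpus.jsonl"
        report_io.write_corpus(reports, corpus_path)
        report_io.write_truth(truths, out_dir / "truth.csv")
    manifest.counts["generated"] = len(reports)
    log.info("simulate: %d reports", len(reports))

    with _Timer(manifest, "parse"):
        read_errors: list[ParseFailure] = []
        raw = report_io.read_corpus(corpus_path, errors=read_errors)
        records, failures = report_io.parse_corpus(raw)
        failures = read_errors + failures
        report_io.write_table(_failures_frame(failures),
                              out_dir / "parse_failures.csv")
    manifest.counts["read"] = len(raw)
    manifest.counts["parsed"] = len(records)
    manifest.counts["parse_failures"] = len(failures)
    log.info("parse: %d parsed, %d failures", len(records), len(failures))
    if strict and failures:
        raise RuntimeError(
            f"strict mode: {len(failures)} record-level failures "
            f"(first: {failures[0].reason})")
    for f in failures:
        log.debug("parse failure %s: %s", f.case_id, f.reason)

    with _Timer(manifest, "classify"):
        classified = classify.classify_cases(records, dictionary)
        df = analytics.cases_to_frame(classified)
        report_io.write_table(df.drop(columns=["is_chp"]),
                              out_dir / "classified.csv")
    manifest.counts["classified"] = len(classified)
    log.info("classify: %d cases", len(classified))

    with _Timer(manifest, "analyze"):
        if classified:
            analyze_cases(classified, out_dir, min_cases=min_cases)

    for path in sorted(out_dir.glob("*.csv")) + [corpus_path]:
        manifest.checksums[path.name] = _sha256(path)
    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n",
                                           encoding="utf-8")
    return manifest
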