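"""End-to-end scan orchestration.

The full method, in run order: harmonize every study to the reference
panel's allele frame; (optionally) impute missing Z-statistics; select
LD-pruned strong instruments; pick causally relevant traits by stepwise
AIC; re-estimate causal effects leaving out each chromosome; build the
per-variant prior table; compute observed Bayes factors; generate pooled
null Bayes factors; assign empirical P values and apply Benjamini-Hochberg.

`run_scan` drives everything from a PipelineConfig of file paths and writes
per-stage artifacts; `run_scan_frames` is the in-memory core used by the
test-suite and by simulation studies.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import ld, mr, prior, sumstats
from . import bfscan as scan_mod

logger = logging.getLogger("priorscan")

__all__ = ["PipelineConfig", "ScanOutput", "run_scan", "run_scan_frames"]


@dataclass
class PipelineConfig:
    """Every knob of the scan, collected in one place.

    Thresholds default to the method's standard settings: instrument
    strength P < 1e-5, LD pruning r^2 <= 0.2, 5% FDR, 1,000 null
    replicates.
    """

    trait_paths: list
    outcome_path: str
    panel_path: str
    out_dir: str
    p_instrument: float = 1e-5
    r2_prune: float = 0.2
    fdr: float = 0.05
    null_k: int = 1000
    null_mode: str = "mvn"
    impute: bool = False
    window_bp: int = 250_000
    ridge: float | None = None
    min_r2pred: float = 0.3
    seed: int = 0

    def validate(self):
        if self.null_k < 1:
            raise ValueError("null_k must be >= 1")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if not 0 < self.p_instrument < 1:
            raise ValueError("p_instrument must lie in (0, 1)")
        if not 0 < self.r2_prune <= 1:
            raise ValueError("r2_prune must lie in (0, 1]")
        for path in [*self.trait_paths, self.outcome_path, self.panel_path]:
            if not Path(path).exists():
                raise FileNotFoundError(path)


@dataclass
class ScanOutput:
    """All stage products of one scan run."""

    result: scan_mod.ScanResult
    priors: prior.PriorTable
    instruments: mr.InstrumentSet
    mr_fit: mr.CausalEffectEstimate
    loco_fits: dict
    null_store: scan_mod.NullBFStore


def run_scan_frames(trait_tables, outcome, panel, p_instrument=1e-5,
                    r2_prune=0.2, fdr=0.05, null_k=1000, null_mode="mvn",
                    seed=0, null_store=None) -> ScanOutput:
    """Run the scan on in-memory tables (already harmonized to the panel).

    ``null_store`` short-circuits null generation when a precomputed store
    for the same priors is supplied.
    """
    inst = mr.select_instruments(trait_tables, outcome, panel,
                                 p_thresh=p_instrument, r2_max=r2_prune)
    fit = mr.stepwise_select(inst)
    loco = mr.loco_estimates(inst, fit.selected_traits)
    priors = prior.build_prior_table(
        trait_tables, loco, outcome.df[["snp", "chr", "pos"]],
        p_thresh=p_instrument)
    n_l = int(outcome.df["n"].iloc[0])
    if null_store is None:
        null_store = scan_mod.generate_null(priors, panel, n_l,
                                            K=null_k, seed=seed,
                                            mode=null_mode)
    result = scan_mod.scan(outcome, priors, null_store, fdr=fdr)
    return ScanOutput(result=result, priors=priors, instruments=inst,
                      mr_fit=fit, loco_fits=loco, null_store=null_store)


def run_scan(config: PipelineConfig) -> ScanOutput:
    """File-driven scan: reads inputs, runs all stages, writes artifacts.

    Artifacts in ``out_dir``: mr_effects.tsv (trait, alpha, se, z, p),
    mr_sidecar.json (covariance, per-chromosome leave-out estimates),
    prior.tsv, scan.tsv, tophits.tsv and run.json (settings + seed).
    Any stage failure aborts with the stage name attached.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        panel = ld.read_panel(config.panel_path)
        outcome = sumstats.read_sumstats(config.outcome_path,
                                         study_id="outcome",
                                         trait_name="outcome")
        traits = [sumstats.read_sumstats(p, study_id=Path(p).stem,
                                         trait_name=Path(p).stem)
                  for p in config.trait_paths]

        stage = "harmonize"
        outcome = sumstats.harmonize(outcome, panel)
        traits = [sumstats.harmonize(t, panel) for t in traits]

        if config.impute:
            stage = "impute"
            targets = panel.variants
            traits = [ld.impute_table(targets, t, panel,
                                      window_bp=config.window_bp,
                                      ridge=config.ridge,
                                      min_r2pred=config.min_r2pred)
                      for t in traits]
            outcome = ld.impute_table(targets, outcome, panel,
                                      window_bp=config.window_bp,
                                      ridge=config.ridge,
                                      min_r2pred=config.min_r2pred)

        stage = "scan"
        out = run_scan_frames(traits, outcome, panel,
                              p_instrument=config.p_instrument,
                              r2_prune=config.r2_prune, fdr=config.fdr,
                              null_k=config.null_k,
                              null_mode=config.null_mode, seed=config.seed)

        stage = "write"
        _write_artifacts(out, config, out_dir)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out


def _write_artifacts(out: ScanOutput, config: PipelineConfig, out_dir: Path):
    out.mr_fit.summary().to_csv(out_dir / "mr_effects.tsv", sep="\t",
                                index=False, float_format="%.10g")
    sidecar = {
        "selected_traits": out.mr_fit.selected_traits,
        "sigma2": out.mr_fit.sigma2,
        "covariance": out.mr_fit.covariance.tolist(),
        "loco": {
            str(c): (f.alpha.tolist()
                     if isinstance(f, mr.CausalEffectEstimate) else str(f))
            for c, f in out.loco_fits.items()
        },
    }
    (out_dir / "mr_sidecar.json").write_text(json.dumps(sidecar, indent=1))
    prior.write_prior_table(out.priors, out_dir / "prior.tsv")
    out.result.df.to_csv(out_dir / "scan.tsv", sep="\t", index=False,
                         float_format="%.10g")
    top = out.result.df[out.result.df["discovery"]][
        ["snp", "chr", "pos", "log_bf", "p_empirical", "q_bh"]].copy()
    top.insert(1, "nearest_gene", "")
    top.to_csv(out_dir / "tophits.tsv", sep="\t", index=False,
               float_format="%.6g")
    run_log = dataclasses.asdict(config)
    run_log["n_discoveries"] = out.result.n_discoveries
    run_log["null_K"] = out.null_store.K
    (out_dir / "run.json").write_text(json.dumps(run_log, indent=1))
    logger.info("scan complete: %d discoveries at FDR %.2g",
                out.result.n_discoveries, config.fdr)
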