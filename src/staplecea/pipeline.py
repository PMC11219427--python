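"""End-to-end pipeline: simulate -> match -> outcomes -> costs -> tree/ICER ->
PSA, with every intermediate artifact written to disk and a manifest recording
seeds, configuration hash and output checksums, so a re-run with the same
configuration reproduces all outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import cohort as cohort_mod
from . import costing, decision, matching, outcomes, psa as psa_mod

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "staplecea_run"
    seed: int = 20210
    n_pool: int = 395
    n_psa: int = 1000
    cohort_csv: str | None = None       # load instead of simulating
    price_table: str | None = None      # YAML; bundled defaults otherwise
    tree_spec: str | None = None        # YAML; estimated from cohort otherwise
    chi2_correction: str = "yates"      # or "pearson"
    welch: bool = False
    caliper: float = 0.2
    caliper_scale: str = "logit-sd"
    skip_matching: bool = False

    def validate(self) -> None:
        if self.n_psa < 1:
            raise ValueError("n_psa must be >= 1")
        if self.n_pool < 2:
            raise ValueError("n_pool must be >= 2")
        for name in ("cohort_csv", "price_table", "tree_spec"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name}: no such file: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the manifest dict.

    Stage failures propagate with the stage name prepended; artifacts written
    before the failure are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "stages": [],
        "outputs": {},
    }

    def record(stage, **info):
        log.info("stage %s: %s", stage, info)
        manifest["stages"].append({"stage": stage, **info})

    stage = "simulate"
    try:
        prices = (
            costing.PriceTable.from_yaml(config.price_table)
            if config.price_table
            else costing.PriceTable()
        )
        if config.cohort_csv:
            pool = cohort_mod.read_cohort(config.cohort_csv)
            record(stage, loaded=config.cohort_csv, n=len(pool))
        else:
            params = cohort_mod.default_params(n_pool=config.n_pool)
            params.to_yaml(out / "cohort_params.yaml")
            pool = cohort_mod.generate_cohort(params, seed=config.seed)
            cohort_mod.write_cohort(pool, out / "cohort.csv")
            record(stage, seed=config.seed, n=len(pool))

        stage = "match"
        if config.skip_matching:
            matched = pool
            record(stage, skipped=True, n=len(matched))
        else:
            scores, coefs = matching.fit_propensity(pool)
            mcfg = matching.MatchConfig(
                caliper=config.caliper, caliper_scale=config.caliper_scale
            )
            pairs = matching.match_one_to_one(pool, scores, mcfg)
            import pandas as pd

            pd.DataFrame(
                [
                    {"treated_id": t, "control_id": c,
                     "score_t": scores[t], "score_c": scores[c]}
                    for t, c in pairs.pairs
                ]
            ).to_csv(out / "pairs.csv", index=False)
            matching.balance_diagnostics(pool, pairs).to_csv(out / "balance.csv")
            matched = matching.matched_cohort(pool, pairs)
            cohort_mod.write_cohort(matched, out / "matched_cohort.csv")
            record(stage, n_pairs=pairs.n_pairs, caliper_width=pairs.caliper_width)

        stage = "outcomes"
        report = outcomes.outcome_report(matched, correction=config.chi2_correction)
        (out / "outcomes.json").write_text(json.dumps(report, indent=2))
        record(stage, leak_p=report["chi_square"]["p_value"])

        stage = "cost"
        costs = costing.cohort_resource_costs(matched, prices)
        costing.group_cost_summary(costs).to_csv(out / "cost_summary.csv")
        costing.per_resource_cost_tests(costs, equal_var=not config.welch).to_csv(
            out / "cost_tests.csv"
        )
        record(stage, n=len(costs))

        stage = "cea"
        tree = (
            decision.read_tree(config.tree_spec)
            if config.tree_spec
            else decision.estimate_tree_parameters(matched)
        )
        decision.write_tree(tree, out / "tree.yaml")
        results = decision.rollback(tree)
        inc = decision.icer(results["ECPS"], results["MCS"])
        cea = {
            arm: {"expected_cost": r.expected_cost,
                  "expected_effectiveness": r.expected_effectiveness}
            for arm, r in results.items()
        }
        cea["icer"] = dataclasses.asdict(inc)
        (out / "cea.json").write_text(json.dumps(cea, indent=2))
        record(stage, icer=inc.icer, dominance=inc.dominance)

        stage = "psa"
        dists = psa_mod.assign_distributions(tree)
        result = psa_mod.run_psa(tree, dists, n=config.n_psa, seed=config.seed + 1)
        result.draws.assign(draw_id=np.arange(result.n)).to_csv(
            out / "psa_draws.csv", index=False
        )
        (out / "psa_summary.json").write_text(json.dumps(result.summary(), indent=2))
        wtp = np.linspace(0, 50_000, 101)
        curve = psa_mod.ceac(result.draws, wtp)
        curve.to_csv(out / "ceac.csv", index=False)
        psa_mod.plot_ce_plane(result.draws, out / "ce_plane.png")
        psa_mod.plot_ceac(curve, out / "ceac.png")
        record(stage, n_draws=result.n, dominant_fraction=result.summary()["dominant_fraction"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for p in sorted(out.iterdir()):
        if p.is_file() and p.suffix != ".png":
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
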