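"""End-to-end orchestration: priors -> consensus -> proportions ->
imputation -> extrapolation, from a single declarative config.

A :class:`PipelineConfig` points either at real CSV inputs (``paths``) or
at a synthetic-data block (``simulate``) — exactly one of the two.  The
run writes publication-shaped CSV outputs (consensus per surveyed region,
regional extrapolations per variant and data mode, stratum-proportion
summaries, national totals) plus a JSON manifest recording every decided
parameter, so a run is reproducible from its manifest and inputs alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import core_data, program_priors, sae
from .consensus import consensus_by_group, default_confidence_scheme, ConfidenceScheme
from .core_data import Dataset
from .synthetic import MethodProfile, SyntheticConfig, generate

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

_POP_SEX = {"FSW": "female", "MSM": "male"}
_VARIANT_COVARIATE = {
    "stratified_hiv": "hiv_prevalence",
    "stratified_density": "population_density",
}


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative pipeline run description (YAML- or dict-loadable)."""

    paths: dict[str, str] | None = None
    simulate: dict[str, Any] | None = None
    populations: tuple[str, ...] = ("FSW",)
    variants: tuple[str, ...] = sae.VARIANTS
    modes: tuple[str, ...] = sae.DATA_MODES
    weights: dict[str, float] | None = None
    fallback_factor: float = 4.0
    prior: str = "per_region"  # per_region | national | none
    survey_year: int = 2014
    target_year: int = 2021
    proportion_age_band: str = "18-49"
    projection_age_band: str = "15-49"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.paths is None) == (self.simulate is None):
            raise ValueError("exactly one of 'paths' and 'simulate' must be set")
        for p in self.populations:
            if p not in core_data.POPULATIONS:
                raise ValueError(f"unknown population {p!r}")
        for v in self.variants:
            if v not in sae.VARIANTS:
                raise ValueError(f"unknown variant {v!r}")
        for m in self.modes:
            if m not in sae.DATA_MODES:
                raise ValueError(f"unknown data mode {m!r}")
        if self.prior not in ("per_region", "national", "none"):
            raise ValueError(f"unknown prior policy {self.prior!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def scheme(self) -> ConfidenceScheme:
        if self.weights is None:
            return default_confidence_scheme()
        return ConfidenceScheme(self.weights, label="user").require_order_preserving()


def _build_dataset(config: PipelineConfig) -> Dataset:
    if config.paths is not None:
        return core_data.load_dataset(config.paths)
    block = dict(config.simulate or {})
    profiles = block.pop("method_profiles", None)
    if profiles is not None:
        block["method_profiles"] = {
            m: MethodProfile(**p) if isinstance(p, dict) else p
            for m, p in profiles.items()
        }
    block.setdefault("seed", config.seed)
    block.setdefault("survey_year", config.survey_year)
    block.setdefault("target_year", config.target_year)
    return generate(SyntheticConfig(**block))


def run_pipeline(
    config: PipelineConfig, output_dir: str | Path | None = None
) -> dict[str, Any]:
    """Run every requested population x variant x mode combination.

    Returns a bundle with the consensus table, the regional extrapolation
    table, the stratum-proportion summary, national totals, the validation
    warnings, and the manifest; when ``output_dir`` is given everything is
    also written as CSV/JSON.
    """
    try:
        dataset = _build_dataset(config)
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc

    warnings_list = core_data.validate_dataset(dataset)
    scheme = config.scheme()

    consensus_frames, extrap_frames, strat_rows, national_rows = [], [], [], []
    for pop in config.populations:
        sex = _POP_SEX[pop]
        est = dataset.direct_estimates
        est = est[est["population"] == pop]
        if est.empty:
            raise PipelineError("consensus", f"no direct estimates for {pop}")
        try:
            denominators = dataset.denominator_series(
                sex, config.proportion_age_band, config.survey_year
            )
            projections = dataset.denominator_series(
                sex, config.projection_age_band, config.target_year
            )
        except KeyError as exc:
            raise PipelineError("denominators", str(exc)) from exc

        # program-data priors
        priors = None
        records = dataset.program_records
        records = records[records["population"] == pop] if not records.empty else records
        if config.prior != "none" and not records.empty:
            try:
                if config.prior == "per_region":
                    by_region = program_priors.priors_by_region(records, pop)
                    priors = {(rid, pop): pr for rid, pr in by_region.items()}
                else:
                    priors = {
                        pop: program_priors.fit_lognormal_prior(
                            program_priors.pool_and_summarize(records, pop)
                        )
                    }
            except Exception as exc:
                raise PipelineError("priors", str(exc)) from exc

        # consensus (used by post_program mode)
        try:
            cons = consensus_by_group(
                est, scheme, priors, fallback_factor=config.fallback_factor
            )
        except Exception as exc:
            raise PipelineError("consensus", str(exc)) from exc
        consensus_frames.append(cons)

        all_regions = list(dataset.regions["region_id"])
        for mode in config.modes:
            try:
                if mode == "post_program":
                    series = cons.set_index("region_id")["point"]
                    props = sae.proportions_from_estimates(
                        series, denominators, pop, source="consensus"
                    )
                else:
                    props = sae.proportions_from_estimates(
                        est, denominators, pop, source="all_estimates"
                    )
            except Exception as exc:
                raise PipelineError("proportions", str(exc)) from exc
            onsample = props.set_index("region_id")["proportion"]

            for variant in config.variants:
                try:
                    if variant == "simple":
                        imputed = sae.simple_impute(onsample, all_regions)
                        strat_summary = {"high": float(imputed.iloc[0]),
                                         "low": float(imputed.iloc[0])}
                    else:
                        var = _VARIANT_COVARIATE[variant]
                        values = dataset.covariate_series(var)
                        values = values.loc[[r for r in all_regions if r in values.index]]
                        missing = set(all_regions) - set(values.index)
                        if missing:
                            raise KeyError(
                                f"missing covariate {var!r} for regions {sorted(missing)}"
                            )
                        _, strata = sae.assign_strata(values, variable=var)
                        imp = sae.StratifiedProportionImputer().fit(strata, onsample)
                        imputed = imp.predict(strata)
                        strat_summary = imp.stratum_means_
                    extrap = sae.extrapolate(
                        imputed, projections, pop, variant=variant, data_mode=mode
                    )
                except Exception as exc:
                    raise PipelineError(f"impute:{variant}:{mode}", str(exc)) from exc
                extrap_frames.append(extrap)
                national_rows.append(
                    {
                        "population": pop,
                        "variant": variant,
                        "data_mode": mode,
                        "national_estimate": sae.national_total(extrap),
                    }
                )
                for stratum in ("high", "low"):
                    strat_rows.append(
                        {
                            "population": pop,
                            "variant": variant,
                            "data_mode": mode,
                            "stratum": stratum,
                            "proportion": strat_summary.get(stratum),
                        }
                    )

    bundle: dict[str, Any] = {
        "consensus": pd.concat(consensus_frames, ignore_index=True),
        "extrapolations": pd.concat(extrap_frames, ignore_index=True),
        "stratum_proportions": pd.DataFrame(strat_rows),
        "national_summary": pd.DataFrame(national_rows),
        "warnings": warnings_list,
        "manifest": _manifest(config, scheme, dataset, warnings_list),
    }
    if output_dir is not None:
        _write_bundle(bundle, Path(output_dir))
    return bundle


def _manifest(config, scheme, dataset: Dataset, warnings_list) -> dict[str, Any]:
    cfg = dataclasses.asdict(config)
    if cfg.get("simulate") and "method_profiles" in (cfg["simulate"] or {}):
        cfg["simulate"]["method_profiles"] = {
            m: dataclasses.asdict(p) if dataclasses.is_dataclass(p) else p
            for m, p in cfg["simulate"]["method_profiles"].items()
        }
    return {
        "config": cfg,
        "confidence_weights": dict(scheme.weights),
        "fallback_factor": config.fallback_factor,
        "rounding": "half_up_at_extrapolation",
        "stratum_tie_rule": "ties_assigned_low",
        "interval_quantile": 1.96,
        "seed": config.seed,
        "record_counts": {k: int(len(v)) for k, v in dataset.tables().items()},
        "n_warnings": len(warnings_list),
    }


def _write_bundle(bundle: dict[str, Any], out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("consensus", "extrapolations", "stratum_proportions", "national_summary"):
        bundle[name].to_csv(out_dir / f"{name}.csv", index=False)
    (out_dir / "warnings.log").write_text(
        "\n".join(bundle["warnings"]) + ("\n" if bundle["warnings"] else ""),
        encoding="utf-8",
    )
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(bundle["manifest"], fh, indent=2, sort_keys=True, default=str)
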