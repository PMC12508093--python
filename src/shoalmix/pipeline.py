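"""One-command orchestration of the full analysis.

``run_full_pipeline`` either reads field tables or simulates synthetic ones,
then runs the three analysis stages — shoal configurations, pairwise
association strengths, and foraging-rate models — writing every stage's
tables plus a run manifest sufficient to reproduce the outputs
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .association import associations_to_frame, association_strength, build_presence_matrix
from .configuration import (
    build_origin_type_table,
    chi_square_2x2,
    classify_all,
    configuration_frequencies,
    fisher_exact_2x2,
    fit_shoal_size_model,
)
from .errors import ConfigError
from .foraging import (
    DesignSpec,
    fit_tweedie_glm,
    group_slopes_and_contrasts,
    profile_power,
    summarize_rates,
)
from .io import (
    STUDY_CATALOG,
    SpeciesCatalog,
    filter_foraging_records,
    read_foraging_table,
    read_shoal_table,
    write_foraging_table,
    write_shoal_table,
)
from .simulate import (
    default_assembly_params,
    default_foraging_params,
    generate_foraging_observations,
    generate_shoal_observations,
    load_params_file,
    make_study_design,
)

log = logging.getLogger("shoalmix")


@dataclass
class PipelineConfig:
    """Inputs, analysis settings and output location of one pipeline run."""

    out_dir: str
    # either provide the two input tables ...
    shoal_table: str | None = None
    foraging_table: str | None = None
    catalog_path: str | None = None
    # ... or simulate them
    simulate: bool = False
    params_file: str | None = None
    n_shoals: int = 250
    n_foraging: int = 294
    # analysis settings
    n_null: int = 1000
    association_method: str = "montecarlo"
    tweedie_power: float = 1.5
    profile_power: bool = False
    ref_shoal_size: float = 3.0
    seed: int | None = None
    verbosity: int = 0

    def validate(self) -> None:
        stochastic = self.simulate or (
            self.association_method == "montecarlo" and self.n_null > 0
        )
        if stochastic and self.seed is None:
            raise ConfigError(
                "a seed is mandatory when any stochastic stage runs "
                "(simulation or Monte-Carlo nulls)"
            )
        if not self.simulate and (self.shoal_table is None or self.foraging_table is None):
            raise ConfigError(
                "provide shoal_table and foraging_table, or set simulate=True"
            )


@dataclass
class ReportBundle:
    """In-memory results of a full pipeline run."""

    classifications: pd.DataFrame
    frequencies_by_origin: pd.DataFrame
    frequencies_by_origin_type: pd.DataFrame
    tests: dict
    size_model: dict
    associations: pd.DataFrame
    bite_fit: dict
    bout_fit: dict
    bite_slopes: pd.DataFrame
    bite_slope_contrasts: pd.DataFrame
    bite_rate_ratios: pd.DataFrame
    rate_summary: pd.DataFrame
    dropped: pd.DataFrame
    manifest: dict


def _json_default(obj: Any):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )


def _fit_payload(fit) -> dict:
    return {
        "response": fit.response,
        "terms": fit.terms,
        "coefficients": fit.coefficients,
        "se": fit.se(),
        "wald_p": fit.wald_p(),
        "power": fit.power,
        "dispersion": fit.dispersion,
        "vcov": fit.vcov.tolist(),
        "deviance": fit.deviance,
        "n_obs": fit.n_obs,
        "df_resid": fit.df_resid,
        "n_iter": fit.n_iter,
        "converged": fit.converged,
        "note": (
            "fixed-effects Tweedie GLM; the original mixed-model random "
            "effects (location, observer, species identity) are not estimated"
        ),
    }


def run_full_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every analysis stage and write the report bundle under out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(3) % (2**31)

    # ---- stage 0: inputs ---------------------------------------------------
    if config.simulate:
        if config.params_file:
            assembly, foraging_params = load_params_file(config.params_file)
        else:
            assembly, foraging_params = (
                default_assembly_params(),
                default_foraging_params(),
            )
        catalog = assembly.catalog
        log.info("simulating %d shoals and %d foraging records", config.n_shoals, config.n_foraging)
        shoals = generate_shoal_observations(
            assembly, config.n_shoals, seed=int(seeds[0])
        )
        design = make_study_design(catalog=catalog, seed=int(seeds[1]))
        if config.n_foraging != len(design):
            design = (design * (config.n_foraging // len(design) + 1))[
                : config.n_foraging
            ]
        foraging = generate_foraging_observations(
            foraging_params, design, seed=int(seeds[1])
        )
        write_shoal_table(shoals, out / "shoals.csv", catalog)
        write_foraging_table(foraging, out / "foraging.csv")
    else:
        catalog = (
            SpeciesCatalog.from_file(config.catalog_path)
            if config.catalog_path
            else STUDY_CATALOG
        )
        shoals = read_shoal_table(config.shoal_table, catalog)
        foraging = read_foraging_table(config.foraging_table)

    # ---- stage 1: shoal configurations ------------------------------------
    log.info("stage 1: shoal configurations (%d shoals)", len(shoals))
    classifications = classify_all(shoals, catalog)
    freq = configuration_frequencies(classifications)
    table = build_origin_type_table(classifications)
    fisher = fisher_exact_2x2(table)
    chi2 = chi_square_2x2(table)
    size_fit = fit_shoal_size_model(classifications)
    tests = {
        "contingency_table": {
            "rows": ["native_only", "range_extending_only"],
            "cols": ["multi_specific", "mono_specific"],
            "counts": [[table.a, table.b], [table.c, table.d]],
        },
        "fisher": {
            "odds_ratio": fisher.odds_ratio,
            "odds_ratio_sample": fisher.odds_ratio_sample,
            "ci95": fisher.ci95,
            "p": fisher.p_value,
            "degenerate": fisher.degenerate,
        },
        "chi_square": {
            "statistic": chi2.statistic,
            "df": chi2.df,
            "p": chi2.p_value,
        },
    }
    size_model = {
        "group_means_log": size_fit.group_means,
        "group_n": size_fit.group_n,
        "letters": size_fit.letters,
        "contrasts": size_fit.contrasts.to_dict(orient="records"),
        "aic_reduced": size_fit.aic_reduced,
        "aic_full": size_fit.aic_full,
    }
    cls_frame = pd.DataFrame(
        [dataclasses.asdict(c) for c in classifications]
    )
    cls_frame.to_csv(out / "classifications.csv", index=False)
    freq.by_origin.to_csv(out / "frequencies_by_origin.csv", index=False)
    freq.by_origin_type.to_csv(out / "frequencies_by_origin_type.csv", index=False)
    _write_json(out / "tests.json", tests)
    _write_json(out / "size_model.json", size_model)

    # ---- stage 2: association strength -------------------------------------
    log.info("stage 2: association strengths (n_null=%d)", config.n_null)
    matrix = build_presence_matrix(shoals, catalog)
    associations = associations_to_frame(
        association_strength(
            matrix,
            n_null=config.n_null,
            method=config.association_method,
            rng=int(seeds[2]),
        )
    )
    associations.to_csv(out / "associations.csv", index=False)

    # ---- stage 3: foraging models ------------------------------------------
    kept, dropped = filter_foraging_records(foraging)
    log.info(
        "stage 3: foraging models (%d records kept, %d dropped)",
        len(kept),
        len(dropped),
    )
    power = config.tweedie_power
    if config.profile_power:
        power, _ = profile_power(kept, catalog)
    bite_fit = fit_tweedie_glm(kept, catalog, response="bite_rate", power=power)
    bout_fit = fit_tweedie_glm(kept, catalog, response="bout_rate", power=power)
    derived = group_slopes_and_contrasts(bite_fit, at_shoal_size=config.ref_shoal_size)
    rate_summary = summarize_rates(kept, catalog)

    _write_json(out / "foraging_fit_bite.json", _fit_payload(bite_fit))
    _write_json(out / "foraging_fit_bout.json", _fit_payload(bout_fit))
    derived.slopes.to_csv(out / "bite_slopes.csv", index=False)
    derived.slope_contrasts.to_csv(out / "bite_slope_contrasts.csv", index=False)
    derived.rate_ratios.to_csv(out / "bite_rate_ratios.csv", index=False)
    rate_summary.to_csv(out / "rate_summary.csv", index=False)
    dropped.to_csv(out / "dropped_records.csv", index=False)

    # ---- manifest -----------------------------------------------------------
    manifest = {
        "shoalmix_version": __version__,
        "numpy_version": np.__version__,
        "config": dataclasses.asdict(config),
        "stage_seeds": [int(s) for s in seeds],
        "n_shoals": len(shoals),
        "n_foraging_records": len(foraging),
        "n_foraging_kept": len(kept),
        "n_foraging_dropped": len(dropped),
        "filters": {
            "min_duration_s": 20.0,
            "min_length_cm": 10.0,
            "max_shoal_size": 50,
        },
    }
    _write_json(out / "manifest.json", manifest)

    return ReportBundle(
        classifications=cls_frame,
        frequencies_by_origin=freq.by_origin,
        frequencies_by_origin_type=freq.by_origin_type,
        tests=tests,
        size_model=size_model,
        associations=associations,
        bite_fit=_fit_payload(bite_fit),
        bout_fit=_fit_payload(bout_fit),
        bite_slopes=derived.slopes,
        bite_slope_contrasts=derived.slope_contrasts,
        bite_rate_ratios=derived.rate_ratios,
        rate_summary=rate_summary,
        dropped=dropped,
        manifest=manifest,
    )


def rerun_from_manifest(manifest_path: str | Path, out_dir: str | Path | None = None) -> ReportBundle:
    """Re-run a pipeline from its manifest alone.

    With the same configuration and seed the outputs are byte-identical.
    """
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    config = PipelineConfig(**manifest["config"])
    if out_dir is not None:
        config.out_dir = str(out_dir)
    return run_full_pipeline(config)
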