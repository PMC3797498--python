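"""Per-layer analysis orchestration: null model -> Mantel grid -> PCNM ->
forward selection -> variation partitioning.

Every stage draws its seed deterministically from one master seed, all
intermediate matrices are written to the output directory as delimited
text, and a machine-readable JSON report collects the stage results with
their settings (permutation counts, scheme, dropped variables), so any
stage can be rerun and checked in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ecoassembly import data as cdata
from ecoassembly.data import (
    CommunityMatrix,
    EnvironmentTable,
    PlotCoordinates,
    ValidationError,
)
from ecoassembly.distance import euclidean_distance, write_distance_matrix
from ecoassembly.mantel import mantel_test, partial_mantel
from ecoassembly.nullmodel import test_mean_deviation, turnover_deviation
from ecoassembly.ordination import forward_select, variation_partitioning
from ecoassembly.pcnm import build_pcnm, write_pcnm_table

logger = logging.getLogger(__name__)

_STAGES = ("null", "mantel", "pcnm", "forward_env", "forward_space", "partition")


@dataclass(frozen=True)
class AnalysisSettings:
    """Settings for one full layer analysis (defaults follow standard usage:
    1000 null-model iterations, 999 permutations, alpha = 0.05, collinearity
    cut at |r| > 0.80)."""

    n_iter_null: int = 1000
    n_perm: int = 999
    alpha: float = 0.05
    r_collinearity: float = 0.80
    scheme: str = "without_replacement"
    seed: int = 0
    env_distance_standardized: bool = True
    double_stop: bool = False
    mantel_tail: str = "greater"


def _stage_seed(master: int, layer: str, stage: str) -> int:
    # zlib.crc32 is stable across processes, unlike built-in str hashing
    import zlib

    key = (zlib.crc32(layer.encode()) % (2**16), _STAGES.index(stage))
    return int(np.random.SeedSequence(master, spawn_key=key).generate_state(1)[0] % (2**31))


@dataclass
class LayerReport:
    """All result objects of one layer analysis, JSON-serializable."""

    layer: str
    settings: AnalysisSettings
    dropped_variables: list
    turnover: dict
    mantel_grid: pd.DataFrame
    forward_env: pd.DataFrame
    forward_space: pd.DataFrame
    partition: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "layer": self.layer,
            "settings": asdict(self.settings),
            "dropped_variables": self.dropped_variables,
            "turnover": self.turnover,
            "mantel": self.mantel_grid.to_dict(orient="records"),
            "forward_selection": {
                "environment": self.forward_env.to_dict(orient="records"),
                "space": self.forward_space.to_dict(orient="records"),
            },
            "partition": self.partition,
            "provenance": self.provenance,
        }

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def prepare_environment(env: EnvironmentTable, aspect_column: str = "aspect") -> EnvironmentTable:
    """Replace a circular aspect column (degrees) by sin/cos components."""
    frame = env.values.copy()
    if aspect_column in frame.columns:
        s, c = cdata.circularize_aspect(frame[aspect_column].to_numpy())
        frame = frame.drop(columns=[aspect_column])
        frame[f"{aspect_column}_sin"] = s
        frame[f"{aspect_column}_cos"] = c
    return EnvironmentTable(frame)


def run_layer(
    community: CommunityMatrix,
    environment: EnvironmentTable,
    coordinates: PlotCoordinates,
    settings: AnalysisSettings | None = None,
    output_dir: str | Path | None = None,
    layer: str = "layer",
) -> LayerReport:
    """Run the full analysis chain for one vegetation layer.

    Stages, in order: aspect circularization -> collinearity filter ->
    z-standardization -> environmental/geographic distances -> null model +
    turnover deviation + t-test -> Mantel / partial-Mantel grid -> PCNM ->
    forward selection (environment block, spatial block) -> variation
    partitioning. Any stage error aborts with the stage name attached.
    """
    settings = settings or AnalysisSettings()
    out = Path(output_dir) if output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise ValidationError(
                f"layer {layer!r}, stage {name!r} failed "
                f"({community.n_plots} plots, {community.n_species} species): {exc}"
            ) from exc

    community, environment, coordinates = cdata.align(community, environment, coordinates)
    environment = stage("aspect", lambda: prepare_environment(environment))
    env_f, dropped = stage(
        "collinearity",
        lambda: cdata.collinearity_filter(environment, settings.r_collinearity),
    )
    env_z = stage("zscore", lambda: cdata.zscore_standardize(env_f))
    env_for_dist = env_z if settings.env_distance_standardized else env_f
    env_d = euclidean_distance(env_for_dist.values)
    geo_d = euclidean_distance(coordinates)

    null_seed = _stage_seed(settings.seed, layer, "null")
    null = stage(
        "null_model",
        lambda: turnover_deviation(
            community, n_iter=settings.n_iter_null, scheme=settings.scheme, seed=null_seed
        ),
    )
    ttest = stage("t_test", lambda: test_mean_deviation(null))

    mantel_seed = _stage_seed(settings.seed, layer, "mantel")
    dev = null.deviation

    def mantel_grid():
        rows = []
        for label, fn in (
            ("EnvD", lambda s: mantel_test(dev, env_d, settings.n_perm, s, settings.mantel_tail)),
            (
                "EnvD|GeoD",
                lambda s: partial_mantel(dev, env_d, geo_d, settings.n_perm, s, settings.mantel_tail),
            ),
            ("GeoD", lambda s: mantel_test(dev, geo_d, settings.n_perm, s, settings.mantel_tail)),
            (
                "GeoD|EnvD",
                lambda s: partial_mantel(dev, geo_d, env_d, settings.n_perm, s, settings.mantel_tail),
            ),
        ):
            res = fn(mantel_seed)
            rows.append(
                {"matrices": label, "R": res.r, "P": res.p_value, "n_perm": res.n_permutations}
            )
        return pd.DataFrame(rows)

    grid = stage("mantel", mantel_grid)

    sef = stage("pcnm", lambda: build_pcnm(coordinates))
    y_hel = stage("hellinger", lambda: cdata.hellinger_transform(community))

    # cap each block so the selected union always fits in the joint model
    # (n > m_E + m_S + 1 is required by the adjusted-R^2 partition)
    per_block_cap = max(1, (community.n_plots - 2) // 2)
    fs_env = stage(
        "forward_env",
        lambda: forward_select(
            y_hel,
            env_z.values,
            alpha=settings.alpha,
            n_perm=settings.n_perm,
            seed=_stage_seed(settings.seed, layer, "forward_env"),
            double_stop=settings.double_stop,
            max_select=per_block_cap,
        ),
    )
    fs_space = stage(
        "forward_space",
        lambda: forward_select(
            y_hel,
            sef.eigenvectors,
            alpha=settings.alpha,
            n_perm=settings.n_perm,
            seed=_stage_seed(settings.seed, layer, "forward_space"),
            double_stop=settings.double_stop,
            max_select=per_block_cap,
        ),
    )

    e_block = env_z.values[fs_env.selected] if fs_env.selected else None
    s_block = sef.eigenvectors[fs_space.selected] if fs_space.selected else None
    if e_block is None and s_block is None:
        partition_dict = {
            "note": "no variables selected in either block; partition undefined",
            "fractions": None,
        }
    else:
        part = stage(
            "partition",
            lambda: variation_partitioning(
                y_hel,
                e_block,
                s_block,
                n_perm=settings.n_perm,
                seed=_stage_seed(settings.seed, layer, "partition"),
            ),
        )
        partition_dict = {
            "fractions": part.fractions(),
            "percents_of_explained": part.percents_of_explained(),
            "adj_r2": {"E": part.adj_r2_E, "S": part.adj_r2_S, "total": part.adj_r2_total},
            "p_values": {
                "E|S": part.p_E_given_S,
                "S|E": part.p_S_given_E,
                "total": part.p_total,
            },
            "n_permutations": part.n_permutations,
        }

    turnover = {
        "mean_observed": float(null.observed.condensed.mean()),
        "mean_expected": float(null.per_iteration_mean.mean()),
        "mean_deviation": ttest.mean_deviation,
        "t": ttest.t_statistic,
        "df": ttest.df,
        "p": ttest.p_value,
        "n_degenerate_pairs": null.n_degenerate,
        "n_iterations": null.n_iterations,
        "scheme": null.scheme,
    }
    provenance = {
        "n_plots": community.n_plots,
        "n_species": community.n_species,
        "n_pcnm_retained": sef.n_retained,
        "truncation_distance_m": sef.truncation_distance,
        "master_seed": settings.seed,
        "stage_seeds": {s: _stage_seed(settings.seed, layer, s) for s in _STAGES},
        "dropped_variables": dropped,
        "env_variables_used": list(env_z.variable_names),
    }
    report = LayerReport(
        layer=layer,
        settings=settings,
        dropped_variables=[list(d) for d in dropped],
        turnover=turnover,
        mantel_grid=grid,
        forward_env=fs_env.to_frame(),
        forward_space=fs_space.to_frame(),
        partition=partition_dict,
        provenance=provenance,
    )
    if out:
        write_distance_matrix(null.observed, out / f"{layer}_observed_bc.csv")
        pd.DataFrame(null.null_mean, index=community.plot_ids, columns=community.plot_ids).to_csv(
            out / f"{layer}_null_mean.csv", index_label="plot"
        )
        write_distance_matrix(dev, out / f"{layer}_deviation.csv")
        write_distance_matrix(env_d, out / f"{layer}_envd.csv")
        write_distance_matrix(geo_d, out / f"{layer}_geod.csv")
        write_pcnm_table(sef, out / f"{layer}_pcnm.csv")
        grid.to_csv(out / f"{layer}_mantel.csv", index=False)
        fs_env.to_frame().to_csv(out / f"{layer}_forward_env.csv", index=False)
        fs_space.to_frame().to_csv(out / f"{layer}_forward_space.csv", index=False)
        report.write(out / f"{layer}_report.json")
        logger.info("layer %s written to %s", layer, out)
    return report


def run_all(
    layers: dict,
    settings: AnalysisSettings | None = None,
    output_dir: str | Path | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Run :func:`run_layer` for every layer and build the cross-layer
    comparison table (mean deviation, Mantel R's, partition fractions).

    ``layers`` maps layer name -> (community, environment, coordinates)
    tuple or :class:`~ecoassembly.simulate.SyntheticDataset`.
    """
    settings = settings or AnalysisSettings()
    reports: dict[str, LayerReport] = {}
    rows = []
    for name, item in layers.items():
        if hasattr(item, "community"):
            comm, env, coords = item.community, item.environment, item.coordinates
        else:
            try:
                comm, env, coords = item
            except Exception as exc:
                raise ValidationError(f"layer {name!r}: expected dataset or 3-tuple") from exc
        rep = run_layer(comm, env, coords, settings, output_dir, layer=name)
        reports[name] = rep
        grid = rep.mantel_grid.set_index("matrices")
        frac = rep.partition.get("fractions") or {}
        rows.append(
            {
                "layer": name,
                "mean_deviation": rep.turnover["mean_deviation"],
                "deviation_p": rep.turnover["p"],
                "mantel_R_EnvD": grid.loc["EnvD", "R"],
                "mantel_R_GeoD": grid.loc["GeoD", "R"],
                "E|S": frac.get("E|S"),
                "E&S": frac.get("E&S"),
                "S|E": frac.get("S|E"),
                "residual": frac.get("residual"),
            }
        )
    summary = pd.DataFrame(rows)
    if output_dir:
        summary.to_csv(Path(output_dir) / "summary.csv", index=False)
    return reports, summary
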