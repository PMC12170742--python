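"""Config-driven scenario runner and the shipped fixture scenarios.

A :class:`ScenarioConfig` names a computation kind (region maps, an
information sweep, an optimal-information scan, a relatedness-value sweep,
or the constant-productivity comparison), its biological parameters and
grid resolutions. ``run_scenario`` executes it deterministically, writing
tab-separated tables, optional vector figures, a structured run log and a
manifest recording the exact configuration and library versions.

The shipped fixtures cover the canonical parameter sets of the study
design: the baseline region maps (a = 0.5, m = 0.35, r = 0.25 at omega in
{0, 16, 512, inf}), the three-column information sweeps at r = 0.5 with m
tied to a by m = 0.6 - a/2, the optimal-information scans, the
relatedness-value sweep and the constant-productivity scenario
(a = 0, m = 1/b - 1) used to compare against symmetric-information models.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import InvalidScenarioError, ModelParams, perfect_info_offer
from .grids import Grids
from .kinship import relatedness_value_table
from .offers import average_preference, no_info_offer, region_map
from .population import (
    DEFAULT_OMEGA_SEARCH,
    InfoCost,
    information_sweep,
    optimal_information_dominant,
    optimal_information_subordinate,
)

__all__ = ["ScenarioConfig", "constraint_m", "run_scenario", "FIXTURES",
           "fixture", "list_fixtures"]

logger = logging.getLogger("repskew.scenarios")

KINDS = (
    "region_maps",
    "perfect_vs_none",
    "preference_regions",
    "information_sweep",
    "optimal_information",
    "relatedness_value",
    "akcay_region_maps",
)


def constraint_m(a: float) -> float:
    """Productivity-balancing intercept m = 0.6 - a/2.

    Ties the minimal helping effect to the quality-productivity coefficient
    so that group productivity at the average quality x = 0.5 stays at 1.6
    (for b = 1) across every a — changing a then rotates the fitness slopes
    without changing their magnitude at the population mean.
    """
    return 0.6 - a / 2.0


@dataclass
class ScenarioConfig:
    """A runnable scenario: parameters, information settings and outputs.

    ``m`` may be given directly or derived via ``m_from_constraint``;
    supplying both is a validation error. ``seed`` is reserved — every
    current computation is deterministic — and is recorded in the manifest.
    """

    name: str
    kind: str = "region_maps"
    b: float = 1.0
    r: float = 0.25
    a: float = 0.5
    m: float | None = None
    m_from_constraint: bool = False
    omegas: tuple = (0.0, 16.0, 512.0, math.inf)
    a_values: tuple | None = None
    r_values: tuple | None = None
    b_values: tuple | None = None
    x_values: tuple = (0.2, 0.5, 0.8)
    cost_per_unit: float = 0.003
    cost_scale: str = "log2"
    aggregation: str = "weighted_mean"
    grid_points: int = 201
    y_coarse: int = 1001
    y_refine_step: float = 1e-5
    outdir: str = "outputs"
    make_figures: bool = True
    seed: int = 0

    # -- derived -----------------------------------------------------------
    def effective_m(self, a: float | None = None) -> float:
        a = self.a if a is None else a
        if self.m_from_constraint:
            return constraint_m(a)
        if self.m is None:
            raise InvalidScenarioError(
                "m is unset: give m or set m_from_constraint"
            )
        return self.m

    def grids(self) -> Grids:
        return Grids.default(self.grid_points, self.y_coarse,
                             self.y_refine_step)

    def params(self, a: float | None = None, r: float | None = None,
               b: float | None = None) -> ModelParams:
        a = self.a if a is None else a
        return ModelParams(
            b=self.b if b is None else b,
            r=self.r if r is None else r,
            a=a,
            m=self.effective_m(a),
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> list[str]:
        """All violations found, as human-readable strings (empty = valid)."""
        problems: list[str] = []
        if self.kind not in KINDS:
            problems.append(f"unknown scenario kind {self.kind!r}")
        akcay = self.kind == "akcay_region_maps"
        if self.m is not None and self.m_from_constraint:
            problems.append(
                "m is both supplied and derived from the constraint; "
                "set exactly one"
            )
        if self.m is None and not self.m_from_constraint and not akcay:
            problems.append("m is unset: give m or set m_from_constraint")
        if akcay and (self.m is not None or self.m_from_constraint):
            problems.append(
                "the constant-productivity scenario fixes m = 1/b - 1; "
                "do not supply m"
            )
        for w in self.omegas:
            if not (float(w) >= 0.0 or math.isinf(float(w))):
                problems.append(f"negative information level omega={w}")
        a_set = self.a_values if self.a_values is not None else (self.a,)
        r_set = self.r_values if self.r_values is not None else (self.r,)
        b_set = self.b_values if self.b_values is not None else (self.b,)
        for b in b_set:
            for a in a_set:
                for r in r_set:
                    if r >= 1.0:
                        problems.append(
                            f"degenerate relatedness r={r}: concession "
                            "solving divides by 1 - r"
                        )
                        continue
                    try:
                        m = (1.0 / b - 1.0) if akcay else self.effective_m(a)
                        ModelParams(b=b, r=r, a=a, m=m)
                    except InvalidScenarioError as err:
                        problems.append(str(err))
        if self.cost_per_unit < 0:
            problems.append("cost_per_unit must be non-negative")
        if self.cost_scale not in ("log2", "linear"):
            problems.append(f"unknown cost_scale {self.cost_scale!r}")
        if self.grid_points < 3:
            problems.append("grid_points must be at least 3")
        return problems

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["omegas"] = ["inf" if math.isinf(float(w)) else float(w)
                       for w in self.omegas]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        data = dict(data)
        for key in ("omegas", "a_values", "r_values", "b_values", "x_values"):
            if data.get(key) is not None:
                data[key] = tuple(float(v) for v in data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# fixtures

def _fixtures() -> dict[str, ScenarioConfig]:
    sweep_omegas = tuple(DEFAULT_OMEGA_SEARCH)
    return {
        "fig1_perfect_vs_none": ScenarioConfig(
            name="fig1_perfect_vs_none", kind="perfect_vs_none", r=0.5,
            m_from_constraint=True, a_values=(-0.5, 0.5, 1.5, 2.0),
        ),
        "fig2_baseline": ScenarioConfig(
            name="fig2_baseline", kind="region_maps", a=0.5, m=0.35, r=0.25,
            omegas=(0.0, 16.0, 512.0, math.inf),
        ),
        "fig3_information_regions": ScenarioConfig(
            name="fig3_information_regions", kind="preference_regions",
            m_from_constraint=True, a_values=(-0.5, 0.5, 1.5),
            r_values=(0.0, 0.25, 0.5, 0.75), omegas=sweep_omegas,
        ),
        "fig4_columns": ScenarioConfig(
            name="fig4_columns", kind="information_sweep", r=0.5,
            m_from_constraint=True, a_values=(-0.5, 0.5, 1.5),
            omegas=sweep_omegas,
        ),
        "fig5_optimal_information": ScenarioConfig(
            name="fig5_optimal_information", kind="optimal_information",
            m_from_constraint=True, a_values=(-0.5, 0.5, 1.5),
            r_values=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
            omegas=sweep_omegas, cost_per_unit=0.003,
            x_values=(0.2, 0.5, 0.8),
        ),
        "fig6_relatedness_value": ScenarioConfig(
            name="fig6_relatedness_value", kind="relatedness_value",
            m_from_constraint=True, a_values=(-0.5, 0.25, 0.5, 1.5),
            x_values=tuple(np.round(np.linspace(0.0, 1.0, 21), 3)),
        ),
        "akcay_comparison": ScenarioConfig(
            name="akcay_comparison", kind="akcay_region_maps", a=0.0,
            r=0.25, m_from_constraint=False, m=None,
            b_values=(0.5, 1.0, 1.5), omegas=(0.0, 16.0, math.inf),
        ),
    }


FIXTURES = _fixtures()


def fixture(name: str) -> ScenarioConfig:
    try:
        return dataclasses.replace(FIXTURES[name])
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None


def list_fixtures() -> list[str]:
    return sorted(FIXTURES)


# ---------------------------------------------------------------------------
# runner

def _omega_tag(w: float) -> str:
    return "inf" if math.isinf(float(w)) else f"{float(w):g}"


def _write(table: pd.DataFrame, path: Path) -> Path:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def run_scenario(config: ScenarioConfig) -> dict:
    """Execute a scenario and write its output bundle.

    Returns the manifest (also written as ``manifest.json``): the
    configuration, a hash of it, grid sizes, library versions, the list of
    files written and per-stage timings. Raises ``InvalidScenarioError``
    listing every violation when the config does not validate.
    """
    problems = config.validate()
    if problems:
        raise InvalidScenarioError(
            "invalid scenario configuration:\n- " + "\n- ".join(problems)
        )
    outdir = Path(config.outdir) / config.name
    outdir.mkdir(parents=True, exist_ok=True)
    grids = config.grids()
    files: list[str] = []
    timings: dict[str, float] = {}

    def stage(label: str, fn):
        t0 = time.perf_counter()
        result = fn()
        timings[label] = round(time.perf_counter() - t0, 4)
        logger.info("scenario=%s stage=%s grid=%dx%d elapsed=%.3fs",
                    config.name, label, grids.nx, grids.nz, timings[label])
        return result

    if config.kind in ("region_maps", "akcay_region_maps"):
        b_set = config.b_values or (config.b,)
        for b in b_set:
            m = (1.0 / b - 1.0) if config.kind == "akcay_region_maps" \
                else config.effective_m()
            params = ModelParams(b=b, r=config.r, a=config.a, m=m)
            for w in config.omegas:
                tag = f"b{b:g}_omega{_omega_tag(w)}" if len(b_set) > 1 \
                    else f"omega{_omega_tag(w)}"
                table = stage(tag, lambda p=params, ww=w:
                              region_map(ww, p, grids))
                files.append(str(_write(table, outdir / f"region_map_{tag}.tsv")))
                if config.make_figures:
                    from .plots import region_heatmap
                    fig_path = outdir / f"region_map_{tag}.svg"
                    region_heatmap(table, str(fig_path),
                                   title=f"{config.name} {tag}")
                    files.append(str(fig_path))

    elif config.kind == "perfect_vs_none":
        for a in config.a_values or (config.a,):
            params = config.params(a=a)
            def build(p=params):
                offers = [perfect_info_offer(float(x), p) for x in grids.x]
                uninformed = no_info_offer(p, grids)
                return pd.DataFrame({
                    "x": grids.x,
                    "share_perfect": [o.share for o in offers],
                    "accepts_perfect": [o.dominant_accepts for o in offers],
                    "dominant_perfect": [o.expected_dominant_inclusive
                                         for o in offers],
                    "share_no_info": uninformed.share,
                    "dominant_alone": p.b + p.r * grids.x,
                })
            table = stage(f"a{a:g}", build)
            files.append(str(_write(table, outdir / f"perfect_vs_none_a{a:g}.tsv")))

    elif config.kind == "preference_regions":
        for a in config.a_values or (config.a,):
            for r in config.r_values or (config.r,):
                params = config.params(a=a, r=r)
                def build(p=params):
                    frames = []
                    for w in config.omegas:
                        frame = average_preference(w, p, grids,
                                                   rule=config.aggregation)
                        frame.insert(0, "omega", float(w))
                        frames.append(frame)
                    return pd.concat(frames, ignore_index=True)
                table = stage(f"a{a:g}_r{r:g}", build)
                files.append(str(_write(
                    table, outdir / f"preference_regions_a{a:g}_r{r:g}.tsv")))

    elif config.kind == "information_sweep":
        for a in config.a_values or (config.a,):
            params = config.params(a=a)
            sweep = stage(f"a{a:g}", lambda p=params:
                          information_sweep(config.omegas, p, grids))
            frame = sweep.to_frame()
            files.append(str(_write(frame, outdir / f"sweep_a{a:g}.tsv")))
            if config.make_figures:
                from .plots import sweep_figure
                fig_path = outdir / f"sweep_a{a:g}.svg"
                sweep_figure(frame, str(fig_path),
                             title=f"a = {a:g}, m = {config.effective_m(a):g}")
                files.append(str(fig_path))

    elif config.kind == "optimal_information":
        cost = InfoCost(config.cost_per_unit, config.cost_scale)
        rows = []
        for a in config.a_values or (config.a,):
            for r in config.r_values or (config.r,):
                params = config.params(a=a, r=r)
                w_dom = stage(f"dom_a{a:g}_r{r:g}", lambda p=params:
                              optimal_information_dominant(
                                  p, grids, cost, config.omegas))
                rows.append({"a": a, "r": r, "party": "dominant",
                             "omega_star": w_dom.omega})
                for x in config.x_values:
                    w_sub = stage(f"sub_a{a:g}_r{r:g}_x{x:g}",
                                  lambda p=params, xx=x:
                                  optimal_information_subordinate(
                                      xx, p, grids, config.omegas))
                    rows.append({"a": a, "r": r,
                                 "party": f"subordinate_x{x:g}",
                                 "omega_star": w_sub.omega})
        table = pd.DataFrame(rows)
        files.append(str(_write(table, outdir / "optimal_information.tsv")))
        if config.make_figures:
            from .plots import optimal_information_figure
            for a in table["a"].unique():
                fig_path = outdir / f"optimal_information_a{a:g}.svg"
                optimal_information_figure(table[table["a"] == a],
                                           str(fig_path), title=f"a = {a:g}")
                files.append(str(fig_path))

    elif config.kind == "relatedness_value":
        table = stage("relatedness_value", lambda: relatedness_value_table(
            config.x_values, config.a_values or (config.a,), grids))
        files.append(str(_write(table, outdir / "relatedness_value.tsv")))
        if config.make_figures:
            from .plots import relatedness_value_figure
            fig_path = outdir / "relatedness_value.svg"
            relatedness_value_figure(table, str(fig_path), title=config.name)
            files.append(str(fig_path))

    config_dict = config.to_dict()
    manifest = {
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "grid": {"nx": grids.nx, "nz": grids.nz, "y_coarse": grids.y_coarse,
                 "y_refine_step": grids.y_refine_step},
        "versions": {
            "repskew": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "files": files,
        "timings_s": timings,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
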