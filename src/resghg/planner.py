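"""Multiobjective dam-portfolio selection on tree-structured river networks.

Candidate dams live on a rooted tree whose nodes are contiguous river
regions and whose edges are the dams, oriented from downstream regions
(outlets) towards upstream regions (sources).  Portfolio objectives are
either sums (hydropower production, firm power) or means (emissions, land
loss) over the selected assets.  The frontier is approximated by a
bottom-up dynamic program: each subtree carries a set of
(portfolio, objective-accumulator) states, children merge by accumulator
addition, and after every merge states are pruned by epsilon-dominance on
objectives normalised to [0, 1].  The pruning grid uses a per-merge cell
size of epsilon / n_assets, so the accumulated error along any root-leaf
composition never exceeds epsilon: every feasible portfolio is
epsilon-dominated (additively, in normalised units) by a returned point.
With epsilon = 0 only exact Pareto filtering is applied and the result is
the exact frontier.

Mean-aggregated objectives are carried as (sum, count) pairs so child
merging stays exact; dominance is only applied between states with equal
selected-asset counts, which keeps pruning safe for means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .emissions import LIFECYCLE_EI_INCREMENT, ROR_BIOGENIC_EI
from .errors import (
    CyclicInput,
    EmptyTree,
    MultipleOutlets,
    NonFiniteMetric,
    SeriesTooShort,
)

__all__ = [
    "AssetMetrics",
    "TreeNetwork",
    "ObjectiveSpec",
    "ParetoPoint",
    "DEFAULT_OBJECTIVES",
    "to_tree",
    "firm_power",
    "epsilon_pareto",
    "frontier_report",
]


@dataclass
class AssetMetrics:
    """Objective-relevant metrics of one hydropower asset.

    Energies in GWh/yr, emissions in tCO2e/yr (one value per estimation
    method), land losses in km2.  Run-of-river assets carry zero land loss
    by definition.
    """

    id: str
    asset_type: str  # "reservoir" or "ror"
    energy: float
    firm_power: float
    emissions: Dict[str, float]  # method ("model" | "ef") -> tCO2e/yr
    cropland_loss: float = 0.0
    forest_loss: float = 0.0
    existing: bool = False

    def __post_init__(self):
        if self.asset_type == "ror" and (self.cropland_loss or self.forest_loss):
            raise ValueError(f"RoR asset {self.id} must have zero land loss")
        values = [self.energy, self.firm_power, self.cropland_loss, self.forest_loss]
        values += list(self.emissions.values())
        if not all(math.isfinite(v) for v in values):
            raise NonFiniteMetric(f"asset {self.id} has a non-finite metric")

    def metric(self, name: str, method: str = "model") -> float:
        if name == "emissions":
            return self.emissions[method]
        if name == "land_loss":
            return self.cropland_loss + self.forest_loss
        return float(getattr(self, name))


@dataclass
class TreeNetwork:
    """Rooted dam-as-edge tree: nodes are river regions, edges carry assets."""

    root: str
    children: Dict[str, List[str]]  # region -> upstream regions
    assets: Dict[Tuple[str, str], AssetMetrics]  # (parent, child) edge -> asset

    def all_assets(self) -> List[AssetMetrics]:
        return [self.assets[e] for e in sorted(self.assets)]

    @property
    def n_assets(self) -> int:
        return len(self.assets)


def to_tree(graph: nx.DiGraph) -> TreeNetwork:
    """Line-graph style transform of a dam-node river graph.

    Input: a directed tree whose nodes carry ``kind`` (``dam`` with an
    ``asset`` attribute, or anything else for junction/outlet/river nodes),
    with edges oriented downstream -> upstream and a single root (the
    outlet).  Dams become edges of the output tree; maximal dam-free
    stretches collapse into single region nodes.
    """
    if not nx.is_directed_acyclic_graph(graph):
        raise CyclicInput("dam-node graph contains a cycle")
    roots = [n for n in graph.nodes if graph.in_degree(n) == 0]
    if len(roots) != 1:
        raise MultipleOutlets(f"expected one outlet, found {len(roots)}: {roots}")

    def is_dam(n) -> bool:
        return graph.nodes[n].get("kind") == "dam"

    # union-find over non-dam nodes joined by dam-free edges
    parent = {n: n for n in graph.nodes if not is_dam(n)}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    for u, v in graph.edges:
        if not is_dam(u) and not is_dam(v):
            union(u, v)

    def region(n):
        return f"region:{find(n)}"

    children: Dict[str, List[str]] = {}
    assets: Dict[Tuple[str, str], AssetMetrics] = {}

    for d in (n for n in graph.nodes if is_dam(n)):
        preds = list(graph.predecessors(d))
        succs = list(graph.successors(d))
        if len(preds) != 1:
            raise CyclicInput(f"dam {d} must have exactly one downstream neighbour")
        down = preds[0]
        if is_dam(down):
            raise CyclicInput(
                f"dams {down} and {d} are directly adjacent; insert a river node"
            )
        # all upstream neighbours of the dam merge into one upstream region
        ups = [s for s in succs if not is_dam(s)]
        if any(is_dam(s) for s in succs):
            raise CyclicInput(f"dam {d} directly upstream-adjacent to another dam")
        if not ups:
            # headwater dam: synthesise an empty source region
            up_name = f"region:src:{d}"
        else:
            for a, b in zip(ups, ups[1:]):
                union(a, b)
            up_name = None  # resolved after all unions
        if "asset" not in graph.nodes[d]:
            raise ValueError(f"dam node {d} carries no 'asset' attribute")
        graph.nodes[d]["_down"] = down
        graph.nodes[d]["_ups"] = ups
        graph.nodes[d]["_srcname"] = up_name

    # resolve names after the union-find is final
    for d in (n for n in graph.nodes if is_dam(n)):
        down = region(graph.nodes[d]["_down"])
        ups = graph.nodes[d]["_ups"]
        up = region(ups[0]) if ups else graph.nodes[d]["_srcname"]
        children.setdefault(down, []).append(up)
        children.setdefault(up, [])
        assets[(down, up)] = graph.nodes[d]["asset"]

    root = region(roots[0])
    children.setdefault(root, [])
    return TreeNetwork(root=root, children=children, assets=assets)


def firm_power(series: Sequence[float], q: float = 5.0,
               periods_per_year: float = 1.0) -> float:
    """Firm power: the ``q``-th percentile of a generation time series.

    The percentile uses the linear-interpolation convention between order
    statistics.  ``periods_per_year`` annualises per-timestep energies
    (e.g. 365.25/7 for weekly series); with the default 1 the series is
    taken to already be in per-year units.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 20:
        raise SeriesTooShort(f"need >= 20 timesteps, got {series.size}")
    return float(np.percentile(series, q, method="linear")) * periods_per_year


@dataclass
class ObjectiveSpec:
    """One selection objective.

    ``sense`` is ``max`` or ``min``; ``aggregation`` is ``sum`` or ``mean``
    over selected assets; ``source`` names an :class:`AssetMetrics` metric
    (``energy``, ``firm_power``, ``emissions``, ``cropland_loss``,
    ``forest_loss``, ``land_loss``); ``method`` selects the emission
    estimation route.
    """

    name: str
    sense: str
    source: str
    aggregation: str = "sum"
    method: str = "model"

    def __post_init__(self):
        if self.sense not in ("max", "min"):
            raise ValueError("sense must be 'max' or 'min'")
        if self.aggregation not in ("sum", "mean"):
            raise ValueError("aggregation must be 'sum' or 'mean'")


#: The five default objectives: maximise energy and firm power, minimise
#: emissions and both land losses.  Emissions default to sum aggregation in
#: reports; mean variants are available per ObjectiveSpec.
DEFAULT_OBJECTIVES = (
    ObjectiveSpec("hp_production", "max", "energy", "sum"),
    ObjectiveSpec("firm_power", "max", "firm_power", "sum"),
    ObjectiveSpec("ghg_emissions", "min", "emissions", "sum"),
    ObjectiveSpec("cropland_loss", "min", "cropland_loss", "mean"),
    ObjectiveSpec("forest_loss", "min", "forest_loss", "mean"),
)


@dataclass
class ParetoPoint:
    """A retained portfolio with its exact objective vector."""

    portfolio: frozenset
    objectives: Dict[str, float]


class _State:
    __slots__ = ("portfolio", "sums", "count")

    def __init__(self, portfolio, sums, count):
        self.portfolio = portfolio
        self.sums = sums  # np.ndarray, minimisation sense, per objective
        self.count = count


def _asset_vector(asset: AssetMetrics, objectives: Sequence[ObjectiveSpec]) -> np.ndarray:
    v = np.empty(len(objectives))
    for i, ob in enumerate(objectives):
        x = asset.metric(ob.source, ob.method)
        v[i] = -x if ob.sense == "max" else x
    return v


def _objective_values(state: _State, objectives) -> np.ndarray:
    """Realised objective values (minimisation sense) of a state."""
    out = state.sums.copy()
    for i, ob in enumerate(objectives):
        if ob.aggregation == "mean":
            out[i] = out[i] / state.count if state.count else 0.0
    return out


def _prune(states: List[_State], objectives, scale: np.ndarray,
           cell: float) -> List[_State]:
    """Exact dominance filter + optional grid pruning, per asset-count group."""
    groups: Dict[int, List[_State]] = {}
    any_mean = any(ob.aggregation == "mean" for ob in objectives)
    for s in states:
        groups.setdefault(s.count if any_mean else 0, []).append(s)
    kept: List[_State] = []
    for group in groups.values():
        vecs = np.array([s.sums for s in group])
        order = np.lexsort(vecs.T[::-1])
        nd: List[int] = []
        for idx in order:
            v = vecs[idx]
            dominated = False
            for j in nd:
                if np.all(vecs[j] <= v) and np.any(vecs[j] < v):
                    dominated = True
                    break
            if not dominated:
                nd = [j for j in nd if not (np.all(v <= vecs[j]) and np.any(v < vecs[j]))]
                nd.append(idx)
        survivors = [group[i] for i in nd]
        if cell > 0:
            boxes: Dict[tuple, _State] = {}
            for s in survivors:
                key = tuple(np.floor(s.sums / (scale * cell)).astype(np.int64))
                cur = boxes.get(key)
                if cur is None or tuple(s.sums) < tuple(cur.sums):
                    boxes[key] = s
            survivors = list(boxes.values())
        kept.extend(survivors)
    return kept


def epsilon_pareto(
    tree: TreeNetwork,
    objectives: Sequence[ObjectiveSpec] = DEFAULT_OBJECTIVES,
    epsilon: float = 0.0,
    scenario: str = "not-built",
) -> List[ParetoPoint]:
    """Approximate the Pareto frontier of dam portfolios on the tree.

    ``scenario='built'`` forces every asset flagged ``existing`` into all
    portfolios; ``'not-built'`` leaves every asset free.  Objective vectors
    of the returned points are recomputed exactly from the portfolios.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if scenario not in ("built", "not-built"):
        raise ValueError("scenario must be 'built' or 'not-built'")
    assets = tree.all_assets()
    if not assets:
        raise EmptyTree("the tree carries no assets")
    n = len(assets)

    # normalisation scale per objective from single-asset extrema: the range
    # of attainable portfolio sums is bounded by the one-signed sums below.
    mat = np.array([_asset_vector(a, objectives) for a in assets])
    hi = np.where(mat > 0, mat, 0.0).sum(axis=0)
    lo = np.where(mat < 0, mat, 0.0).sum(axis=0)
    scale = np.maximum(hi - lo, 1e-300)
    cell = (epsilon / n) if epsilon > 0 else 0.0

    asset_vec = {a.id: _asset_vector(a, objectives) for a in assets}
    forced = {a.id for a in assets if scenario == "built" and a.existing}
    n_obj = len(objectives)

    def edge_states(asset: AssetMetrics, child_states: List[_State]) -> List[_State]:
        out = []
        v = asset_vec[asset.id]
        for s in child_states:
            # select the dam
            out.append(_State(s.portfolio | {asset.id}, s.sums + v, s.count + 1))
            if asset.id not in forced:
                out.append(s)
        return out

    def subtree(node: str) -> List[_State]:
        states = [_State(frozenset(), np.zeros(n_obj), 0)]
        for child in tree.children.get(node, []):
            asset = tree.assets[(node, child)]
            child_st = edge_states(asset, subtree(child))
            merged = [
                _State(s.portfolio | c.portfolio, s.sums + c.sums, s.count + c.count)
                for s in states
                for c in child_st
            ]
            states = _prune(merged, objectives, scale, cell)
        return states

    # final filter: global exact dominance on the *realised* objective values
    # (means evaluated), across asset counts
    states = subtree(tree.root)
    realised = np.array([_objective_values(s, objectives) for s in states])
    final = []
    for i, s in enumerate(states):
        v = realised[i]
        dom = np.all(realised <= v, axis=1) & np.any(realised < v, axis=1)
        if not dom.any():
            final.append(s)

    points = []
    by_id = {a.id: a for a in assets}
    for s in sorted(final, key=lambda st: tuple(st.sums)):
        vals = {}
        sel = [by_id[i] for i in s.portfolio]
        for ob in objectives:
            xs = [a.metric(ob.source, ob.method) for a in sel]
            if ob.aggregation == "sum":
                vals[ob.name] = float(sum(xs))
            else:
                vals[ob.name] = float(np.mean(xs)) if xs else 0.0
        points.append(ParetoPoint(portfolio=s.portfolio, objectives=vals))
    return points


def frontier_report(
    frontier: Sequence[ParetoPoint],
    tree: TreeNetwork,
    method: str = "model",
    lifecycle: bool = False,
) -> pd.DataFrame:
    """Tabulate a frontier: totals, emission intensity, firm-power ratio.

    Emission intensity is total emissions over total generation (g/kWh;
    tCO2e/yr over GWh/yr is exactly g/kWh), with RoR assets contributing at
    the constant biogenic intensity.  Sorted by hydropower production.
    """
    by_id = {a.id: a for a in tree.all_assets()}
    rows = []
    for pt in frontier:
        sel = [by_id[i] for i in sorted(pt.portfolio)]
        energy = sum(a.energy for a in sel)
        firm = sum(a.firm_power for a in sel)
        emissions = sum(
            a.emissions[method] if a.asset_type != "ror"
            else ROR_BIOGENIC_EI * a.energy  # g/kWh x GWh/yr = t/yr
            for a in sel
        )
        ei = emissions / energy if energy > 0 else 0.0
        if lifecycle and energy > 0:
            ei += LIFECYCLE_EI_INCREMENT
        rows.append(
            {
                "n_assets": len(sel),
                "hp_production_gwh": energy,
                "firm_power_gwh": firm,
                "total_emissions_t": emissions,
                "emission_intensity_g_per_kwh": ei,
                "firm_power_ratio": firm / energy if energy > 0 else 0.0,
                "cropland_loss_km2": sum(a.cropland_loss for a in sel),
                "forest_loss_km2": sum(a.forest_loss for a in sel),
                "portfolio": ";".join(sorted(pt.portfolio)),
            }
        )
    return pd.DataFrame(rows).sort_values("hp_production_gwh").reset_index(drop=True)
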