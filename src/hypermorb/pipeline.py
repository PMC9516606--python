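"""Orchestration of the full multimorbidity-cluster analysis.

Given a cohort and its CAL quartile assignment, the pipeline builds one
weighted hypergraph per stratum — overall, each quartile, and optionally
covariate levels within the extreme quartiles — and reports, per stratum:
single-disease (node-level) eigenvector centralities, cluster-level
(dual-hypergraph) centralities, the pairwise co-occurrence count matrix
behind the heat maps, and the top overlap-weighted clusters behind the
bar plots. Two sensitivity modes rerun everything with a survey cycle
removed or with missing diagnoses recoded as positive.

Hypergraphs are rebuilt per stratum from that stratum's participants
only, so all weights (W_E, W_N) are stratum-local.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cohort import CYCLE_LEVELS, CohortTable
from .errors import ConfigurationError, DegenerateGraphError
from .hypergraph import (AdjacencyMatrix, CentralityTable, Hyperedge,
                         build_incidence, dual_adjacency, eigenvector_centrality,
                         node_adjacency, rank_centralities)
from .perio import QuartileAssignment

StratifyVariable = Literal["ethnicity", "smoking", "income"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline options.

    ``income_low`` / ``income_high`` define the dichotomized household-income
    strata (default: quintiles {1,2} = low, {4,5} = high, middle excluded).
    ``min_edge_support`` drops clusters observed in fewer participants.
    ``top_k`` bounds the bar-plot cluster list.
    """

    income_low: tuple[int, ...] = (1, 2)
    income_high: tuple[int, ...] = (4, 5)
    min_edge_support: int = 1
    edge_universe: Literal["profiles", "subsets"] = "profiles"
    counting: Literal["superset", "exact"] = "superset"
    top_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_edge_support < 1:
            raise ConfigurationError("min_edge_support must be >= 1")
        if set(self.income_low) & set(self.income_high):
            raise ConfigurationError("income strata must be disjoint")


@dataclass
class StratumResult:
    """Everything computed for one stratum of the cohort."""

    name: str
    n_participants: int
    n_edges: int
    node_centrality: CentralityTable | None
    dual_centrality: CentralityTable | None
    cooccurrence: np.ndarray
    disease_labels: tuple[str, ...]
    top_clusters: list[Hyperedge]
    skipped: bool = False
    skip_reason: str | None = None


@dataclass
class AnalysisReport:
    """Per-stratum results plus provenance (config, counts, warnings)."""

    strata: dict[str, StratumResult]
    provenance: dict

    def to_dict(self) -> dict:
        """Deterministic JSON-serializable form (byte-identical for equal inputs)."""
        out: dict = {"provenance": self.provenance, "strata": {}}
        for name in sorted(self.strata):
            s = self.strata[name]
            entry: dict = {
                "n_participants": s.n_participants,
                "n_edges": s.n_edges,
                "skipped": s.skipped,
                "skip_reason": s.skip_reason,
                "cooccurrence": {
                    "labels": list(s.disease_labels),
                    "counts": [[int(v) for v in row] for row in s.cooccurrence],
                },
                "top_clusters": [
                    {"diseases": list(e.diseases), "member_count": e.member_count,
                     "weight": float(e.weight)}
                    for e in s.top_clusters
                ],
            }
            for key, tab in (("node_centrality", s.node_centrality),
                             ("dual_centrality", s.dual_centrality)):
                entry[key] = None if tab is None else {
                    "eigenvalue": float(tab.eigenvalue),
                    "ranking": [
                        {"label": lab, "centrality": val, "rank": rank}
                        for lab, val, rank in rank_centralities(tab)
                    ],
                }
            out["strata"][name] = entry
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def write_dir(self, out_dir: str | Path) -> None:
        """Write per-stratum CSV tables and a provenance JSON under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in sorted(self.strata):
            s = self.strata[name]
            tag = name.replace("/", "__").replace("=", "-")
            if s.node_centrality is not None:
                _centrality_csv(s.node_centrality).to_csv(
                    out / f"centrality_nodes_{tag}.csv", index=False)
            if s.dual_centrality is not None:
                _centrality_csv(s.dual_centrality).to_csv(
                    out / f"centrality_dual_{tag}.csv", index=False)
            pd.DataFrame(s.cooccurrence, index=list(s.disease_labels),
                         columns=list(s.disease_labels)).to_csv(
                out / f"cooccurrence_{tag}.csv")
            pd.DataFrame([
                {"cluster": e.label, "size": len(e.diseases),
                 "member_count": e.member_count, "weight": e.weight}
                for e in s.top_clusters
            ]).to_csv(out / f"top_clusters_{tag}.csv", index=False)
        (out / "provenance.json").write_text(
            json.dumps({"provenance": self.provenance}, sort_keys=True, indent=2))


def _centrality_csv(table: CentralityTable) -> pd.DataFrame:
    rows = [{"label": lab, "centrality": val, "centrality_2dp": round(val, 2),
             "rank": rank} for lab, val, rank in rank_centralities(table)]
    return pd.DataFrame(rows)


def cooccurrence_counts(matrix: np.ndarray) -> np.ndarray:
    """Disease x disease co-occurrence counts; the diagonal holds case counts."""
    m = np.asarray(matrix, dtype=np.int64)
    return m.T @ m


def top_weighted_clusters(edges: Sequence[Hyperedge], k: int) -> list[Hyperedge]:
    """Top-k clusters by overlap weight; ties by support then canonical set order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(edges, key=lambda e: (-e.weight, -e.member_count,
                                           len(e.indices), e.indices))
    return ordered[:k]


def _analyze_stratum(name: str, matrix: np.ndarray, labels: tuple[str, ...],
                     config: AnalysisConfig) -> StratumResult:
    cooc = cooccurrence_counts(matrix)
    represented = int((matrix.sum(axis=0) >= 1).sum())
    if matrix.shape[0] == 0 or represented < 2:
        return StratumResult(name=name, n_participants=int(matrix.shape[0]),
                             n_edges=0, node_centrality=None, dual_centrality=None,
                             cooccurrence=cooc, disease_labels=labels, top_clusters=[],
                             skipped=True,
                             skip_reason=f"only {represented} disease(s) represented")

    from .catalog import DiseaseCatalog
    inc = build_incidence(matrix, DiseaseCatalog(labels),
                          edge_universe=config.edge_universe,
                          counting=config.counting,
                          min_support=config.min_edge_support)
    node_tab = dual_tab = None
    try:
        node_tab = eigenvector_centrality(node_adjacency(inc))
    except DegenerateGraphError:
        pass
    try:
        dual_tab = eigenvector_centrality(dual_adjacency(inc))
    except DegenerateGraphError:
        pass
    return StratumResult(name=name, n_participants=int(matrix.shape[0]),
                         n_edges=inc.n_edges, node_centrality=node_tab,
                         dual_centrality=dual_tab, cooccurrence=cooc,
                         disease_labels=labels,
                         top_clusters=top_weighted_clusters(inc.edges, config.top_k)
                         if inc.n_edges else [])


def _quartile_vector(table: CohortTable, quartiles: QuartileAssignment) -> np.ndarray:
    ids = table.frame["participant_id"].astype(str)
    return np.array([quartiles.labels.get(pid, 0) for pid in ids])


def quartile_analysis(table: CohortTable, quartiles: QuartileAssignment,
                      config: AnalysisConfig = AnalysisConfig()) -> AnalysisReport:
    """Overall + per-CAL-quartile hypergraph analysis.

    Each stratum's hypergraph is built from that stratum's participants
    only. Strata with fewer than two represented diseases are skipped and
    the reason recorded in provenance.
    """
    labels = tuple(table.catalog.names)
    q = _quartile_vector(table, quartiles)
    matrix = table.binarize()

    strata: dict[str, StratumResult] = {
        "overall": _analyze_stratum("overall", matrix, labels, config)}
    for k in (1, 2, 3, 4):
        strata[f"quartile_{k}"] = _analyze_stratum(
            f"quartile_{k}", matrix[q == k], labels, config)

    return AnalysisReport(strata=strata, provenance=_provenance(
        table, config, {name: s.n_participants for name, s in strata.items()},
        [f"{s.name}: {s.skip_reason}" for s in strata.values() if s.skipped]))


def stratified_analysis(table: CohortTable, quartiles: QuartileAssignment,
                        variable: StratifyVariable,
                        config: AnalysisConfig = AnalysisConfig()) -> AnalysisReport:
    """Covariate-stratified analysis within the first and fourth CAL quartiles.

    ``variable`` is one of ``ethnicity`` (white / other), ``smoking``
    (smoker / nonsmoker) or ``income`` (low / high quintile groups; the
    middle quintile is excluded by default). Participants with a missing
    value of the variable are excluded and counted in provenance.
    """
    frame = table.frame
    if variable == "ethnicity":
        levels = {"white": frame["ethnicity"] == "white",
                  "other": frame["ethnicity"] == "other"}
    elif variable == "smoking":
        levels = {"smoker": frame["smoker"] == "yes",
                  "nonsmoker": frame["smoker"] == "no"}
    elif variable == "income":
        inc = frame["income_quintile"]
        levels = {"low": inc.isin(config.income_low),
                  "high": inc.isin(config.income_high)}
    else:
        raise ConfigurationError(f"unknown stratification variable {variable!r}")

    labels = tuple(table.catalog.names)
    q = _quartile_vector(table, quartiles)
    matrix = table.binarize()
    covered = np.zeros(len(frame), dtype=bool)

    strata: dict[str, StratumResult] = {}
    warnings: list[str] = []
    for k in (1, 4):
        for level, mask in levels.items():
            sel = (q == k) & mask.to_numpy()
            covered |= mask.to_numpy()
            name = f"quartile_{k}/{variable}={level}"
            if not sel.any():
                warnings.append(f"{name}: empty level, skipped")
                continue
            strata[name] = _analyze_stratum(name, matrix[sel], labels, config)
            if strata[name].skipped:
                warnings.append(f"{name}: {strata[name].skip_reason}")
    n_uncovered = int((~covered).sum())
    if n_uncovered:
        warnings.append(
            f"{n_uncovered} participant(s) outside the {variable} strata "
            "(missing value or excluded level)")
    return AnalysisReport(strata=strata, provenance=_provenance(
        table, config, {name: s.n_participants for name, s in strata.items()},
        warnings, variable=variable))


def sensitivity_run(table: CohortTable, quartiles: QuartileAssignment,
                    mode: tuple[str, str] | str,
                    config: AnalysisConfig = AnalysisConfig()) -> AnalysisReport:
    """Rerun the quartile analysis under a sensitivity scenario.

    ``mode`` is either ``("drop_cycle", cycle)`` — remove that survey
    cycle's participants — or ``"missing_positive"`` — recode missing
    diagnosis flags as positive. Everything else is identical to the
    baseline; the report's provenance records the mode.
    """
    if isinstance(mode, tuple) and len(mode) == 2 and mode[0] == "drop_cycle":
        cycle = mode[1]
        if cycle not in CYCLE_LEVELS:
            raise ConfigurationError(f"unknown survey cycle {cycle!r}")
        sub = table.subset((table.frame["cycle"] != cycle).to_numpy())
        report = quartile_analysis(sub, quartiles, config)
        report.provenance["sensitivity_mode"] = f"drop_cycle:{cycle}"
    elif mode == "missing_positive":
        recoded = replace(table, missing_policy="present")
        report = quartile_analysis(recoded, quartiles, config)
        report.provenance["sensitivity_mode"] = "missing_positive"
    else:
        raise ConfigurationError(f"unknown sensitivity mode {mode!r}")
    return report


def _provenance(table: CohortTable, config: AnalysisConfig,
                counts: dict[str, int], warnings: list[str],
                **extra) -> dict:
    prov = {
        "n_input_participants": table.n,
        "missing_policy": table.missing_policy,
        "config": {
            "income_low": list(config.income_low),
            "income_high": list(config.income_high),
            "min_edge_support": config.min_edge_support,
            "edge_universe": config.edge_universe,
            "counting": config.counting,
            "top_k": config.top_k,
            "seed": config.seed,
        },
        "stratum_sizes": counts,
        "warnings": warnings,
        "sensitivity_mode": None,
    }
    prov.update(extra)
    return prov
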