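"""Multi-run CAE (mrCAE): run aggregation, frequency tables and stable sets.

A single CAE run is stochastic: different seeds select different, comparably
informative feature subsets. The multi-run system trains R independent CAEs
and ranks features by the number of runs in which they appear; features with
high cross-run frequency form the *stable set*. Ranking is by raw frequency
with ties broken by feature ID (ascending) so that every report is
deterministic.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .cae import CAEConfig, RunResult, train_cae
from .data_io import ExpressionMatrix, LabelVector


@dataclass
class FrequencyTable:
    """Cross-run selection counts: feature ID -> number of runs selecting it."""

    counts: dict[str, int]
    total_runs: int

    def __post_init__(self) -> None:
        bad = {f: c for f, c in self.counts.items() if not 1 <= c <= self.total_runs}
        if bad:
            raise ValueError(f"counts outside [1, total_runs]: {bad}")


@dataclass
class StableFeatureSet:
    """Top-N features ranked by cross-run frequency."""

    ranked: list[tuple[str, int]]
    n_requested: int
    tie_rule: str = "feature_id_ascending"

    @property
    def feature_ids(self) -> list[str]:
        return [f for f, _ in self.ranked]

    def as_set(self) -> set[str]:
        return set(self.feature_ids)


def run_mrcae(
    m: ExpressionMatrix,
    cfg: CAEConfig,
    n_runs: int,
    base_seed: int,
    labels: LabelVector | None = None,
    out_dir: str | Path | None = None,
) -> list[RunResult]:
    """Train ``n_runs`` independent CAEs; run ``i`` uses seed ``base_seed + i``.

    When ``out_dir`` is given each run is persisted as ``run_<seed>.json`` as
    soon as it finishes, and already-persisted runs are loaded instead of
    retrained, so interrupted jobs resume and R-run systems can reuse a common
    pool of runs as nested prefixes.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    results: list[RunResult] = []
    for i in range(n_runs):
        seed = base_seed + i
        cache = out_path / f"run_{seed}.json" if out_path is not None else None
        if cache is not None and cache.exists():
            results.append(RunResult.from_dict(json.loads(cache.read_text())))
            continue
        try:
            result = train_cae(m, replace(cfg, seed=seed), labels=labels)
        except Exception as exc:  # annotate with run index, keep the traceback
            raise RuntimeError(f"mrCAE run {i} (seed {seed}) failed: {exc}") from exc
        if cache is not None:
            cache.write_text(json.dumps(result.to_dict()))
        results.append(result)
    return results


def build_frequency_table(runs: list[RunResult]) -> FrequencyTable:
    """Tally, per feature, the number of runs whose unique set contains it.

    A feature picked by several selector nodes within one run counts once for
    that run; deduplication happens in ``RunResult.selected_unique``.
    """
    if not runs:
        raise ValueError("need at least one run")
    counts: Counter[str] = Counter()
    for run in runs:
        counts.update(run.selected_unique)
    return FrequencyTable(counts=dict(counts), total_runs=len(runs))


def top_n(table: FrequencyTable, n: int) -> StableFeatureSet:
    """The N most frequent features, ties broken by feature ID ascending."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(table.counts.items(), key=lambda fc: (-fc[1], fc[0]))
    return StableFeatureSet(ranked=ranked[:n], n_requested=n)


def frequent_features(table: FrequencyTable, min_count: int = 2) -> set[str]:
    """Features appearing in at least ``min_count`` runs ("frequent" features)."""
    return {f for f, c in table.counts.items() if c >= min_count}


def stability_report(
    tables: list[FrequencyTable], top_sizes: list[int]
) -> pd.DataFrame:
    """Per-system summary statistics and Top-N frequency ranges.

    One row per (system, scope): scope ``all`` gives the total number of
    distinct features with the min/max cross-run frequency; scope ``top_N``
    gives the frequency range within the Top-N ranking.
    """
    rows = []
    for table in tables:
        freqs = sorted(table.counts.values())
        rows.append(
            {
                "n_runs": table.total_runs,
                "scope": "all",
                "n_features": len(table.counts),
                "min_freq": freqs[0],
                "max_freq": freqs[-1],
            }
        )
        for n in top_sizes:
            sel = top_n(table, n)
            top_freqs = [c for _, c in sel.ranked]
            rows.append(
                {
                    "n_runs": table.total_runs,
                    "scope": f"top_{n}",
                    "n_features": len(top_freqs),
                    "min_freq": min(top_freqs),
                    "max_freq": max(top_freqs),
                }
            )
    return pd.DataFrame(rows)


def consensus_union(stable_sets: list[StableFeatureSet]) -> set[str]:
    """Union of the member features of several stable sets."""
    if not stable_sets:
        raise ValueError("need at least one stable set")
    out: set[str] = set()
    for s in stable_sets:
        out |= s.as_set()
    return out


def write_stable_set(s: StableFeatureSet, path: str | Path) -> None:
    pd.DataFrame(s.ranked, columns=["feature_id", "frequency"]).to_csv(
        path, sep="\t", index=False
    )


def read_feature_set(path: str | Path) -> set[str]:
    """Read a feature set from a one- or two-column TSV (header optional)."""
    df = pd.read_csv(path, sep="\t")
    col = "feature_id" if "feature_id" in df.columns else df.columns[0]
    return set(df[col].astype(str))
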