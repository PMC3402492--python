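"""Priming effects, transition statistics and the spreading-activation wave.

The priming effect of a cell is the mean RT to unrelated targets minus the
mean RT to related (or indirectly related) targets, computed within
matched condition x SOA x Type-I-ratio cells; non-converged trials are
excluded from RT means but counted. The statistical spreading-activation
wave is the across-trial mean correlation of the semantic network state
with probe patterns at fixed times after prime onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PrimingSummary",
    "priming_effects",
    "transition_histogram",
    "spreading_wave",
]

_CELL_KEYS = ["condition", "soa", "ratio", "relatedness"]


@dataclass
class PrimingSummary:
    """Tabulated priming results of one or more experiment grids.

    Attributes
    ----------
    cell_stats
        Per-cell trial count, converged count, mean and std of RT.
    priming
        One row per (condition, soa, ratio, kind) with the priming effect
        in ms and its standard error (kind is "direct" or "indirect").
    condition_means
        Priming averaged across Type-I ratios per (condition, soa, kind).
    aggregates
        Summary aggregates: short-SOA direct priming averaged over the
        high (0.75, 1) and low (0, 0.25) Type-I ratio pairs separately,
        plus the across-ratio indirect and long-SOA averages, per condition.
    """

    cell_stats: pd.DataFrame
    priming: pd.DataFrame
    condition_means: pd.DataFrame
    aggregates: pd.DataFrame

    def mean_priming(self, condition: str, soa: float, kind: str = "direct") -> float:
        """Across-ratio mean priming effect [ms] for one condition and SOA."""
        cm = self.condition_means
        row = cm[
            (cm.condition == condition) & (cm.soa == soa) & (cm.kind == kind)
        ]
        if row.empty:
            raise KeyError(f"no {kind} priming for {condition} at SOA {soa}")
        return float(row.priming_ms.iloc[0])


def priming_effects(records_or_frame) -> PrimingSummary:
    """Compute direct and indirect priming effects from trial records."""
    df = _as_frame(records_or_frame)
    ok = df[df.converged]
    stats = (
        df.groupby(_CELL_KEYS, dropna=False)
        .agg(
            n=("rt_ms", "size"),
            n_converged=("converged", "sum"),
            mean_rt=("rt_ms", lambda s: s[df.loc[s.index, "converged"]].mean()),
            std_rt=("rt_ms", lambda s: s[df.loc[s.index, "converged"]].std()),
        )
        .reset_index()
    )

    cells = ok.groupby(_CELL_KEYS)["rt_ms"].agg(["mean", "var", "count"])
    rows = []
    for (condition, soa, ratio), sub in cells.groupby(level=[0, 1, 2]):
        sub = sub.droplevel([0, 1, 2])
        if "unrelated" not in sub.index:
            raise ValueError(
                f"missing unrelated cell for condition={condition}, "
                f"soa={soa}, ratio={ratio}"
            )
        unrel = sub.loc["unrelated"]
        for relatedness, kind in (("related", "direct"), ("indirect", "indirect")):
            if relatedness not in sub.index:
                continue
            rel = sub.loc[relatedness]
            rows.append(
                {
                    "condition": condition,
                    "soa": soa,
                    "ratio": ratio,
                    "kind": kind,
                    "priming_ms": unrel["mean"] - rel["mean"],
                    "se_ms": np.sqrt(
                        unrel["var"] / unrel["count"] + rel["var"] / rel["count"]
                    ),
                }
            )
    if not rows:
        raise ValueError("no matched related/unrelated cells in the records")
    priming = pd.DataFrame(rows)

    condition_means = (
        priming.groupby(["condition", "soa", "kind"])["priming_ms"]
        .mean()
        .reset_index()
    )

    agg_rows = []
    for condition, sub in priming.groupby("condition"):
        short_direct = sub[(sub.soa == 200.0) & (sub.kind == "direct")]
        for label, band in (("direct_short_typeI", (0.75, 1.0)),
                            ("direct_short_typeII", (0.0, 0.25))):
            vals = short_direct[short_direct.ratio.isin(band)].priming_ms
            if len(vals):
                agg_rows.append(
                    {"condition": condition, "measure": label,
                     "priming_ms": vals.mean()}
                )
        for label, soa, kind in (
            ("indirect_short", 200.0, "indirect"),
            ("direct_long", 950.0, "direct"),
        ):
            vals = sub[(sub.soa == soa) & (sub.kind == kind)].priming_ms
            if len(vals):
                agg_rows.append(
                    {"condition": condition, "measure": label,
                     "priming_ms": vals.mean()}
                )
    aggregates = pd.DataFrame(agg_rows)

    return PrimingSummary(
        cell_stats=stats,
        priming=priming,
        condition_means=condition_means,
        aggregates=aggregates,
    )


def transition_histogram(
    records_or_frame, keys: tuple[str, ...] = ("condition", "soa")
) -> pd.DataFrame:
    """Normalized distribution of semantic transition counts per group.

    Returns a frame indexed by ``n_transitions`` with one column per group,
    each column summing to 1.
    """
    df = _as_frame(records_or_frame)
    counts = (
        df.groupby(list(keys))["n_transitions"]
        .value_counts(normalize=True)
        .rename("frequency")
        .reset_index()
    )
    table = counts.pivot_table(
        index="n_transitions",
        columns=list(keys),
        values="frequency",
        fill_value=0.0,
    )
    return table.sort_index()


def spreading_wave(
    wave: np.ndarray,
    primes: np.ndarray,
    prime_index: int,
    probe_patterns: tuple[int, ...],
) -> np.ndarray:
    """Across-trial mean correlation with probe patterns at the probe times.

    ``wave``: (n_trials, n_times, n_patterns) correlation snapshots (as
    produced by :func:`latchnet.experiment.run_wave_trials`); only trials
    whose prime equals ``prime_index`` enter the average. Returns an array
    of shape ``(len(probe_patterns), n_times)``.
    """
    primes = np.asarray(primes)
    mask = primes == prime_index
    if not mask.any():
        raise ValueError(f"no trials with prime {prime_index}")
    mean = np.nanmean(wave[mask], axis=0)  # (n_times, n_patterns)
    return mean[:, list(probe_patterns)].T


def _as_frame(records_or_frame) -> pd.DataFrame:
    if isinstance(records_or_frame, pd.DataFrame):
        return records_or_frame
    from .experiment import records_to_frame

    return records_to_frame(records_or_frame)
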