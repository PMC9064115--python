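"""Differential abundance (Mann-Whitney U) and differential presence
(Fisher exact) testing with Benjamini-Hochberg FDR control.

Abundance mode tests each taxon's relative abundances between cases and
controls with a two-sided Mann-Whitney U test; presence mode binarizes the
profiles at a detection threshold and tests the 2x2 presence table with a
two-sided Fisher exact test. Both p-value vectors are FDR-adjusted across
taxa within one cohort and one mode, and taxa with q below alpha get an
enrichment direction (higher-prevalence group in presence mode, higher
mean-rank group in abundance mode). A concordance report quantifies how
well the two modes agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .degradation import binarize
from .profiles_io import LabeledCohort, ProfileError, TaxonLineage

_EXACT_MAX_N = 8  # exact MWU enumeration below this group size (tie-free only)


def mannwhitney_test(case_values: np.ndarray, control_values: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value for a taxon's abundances.

    Exact (full enumeration of rank assignments) when the smaller group has
    at most 8 observations and there are no ties; otherwise a tie-corrected
    normal approximation with continuity correction.
    """
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if case_values.size == 0 or control_values.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([case_values, control_values])
    if np.unique(pooled).size == 1:
        return 1.0  # constant taxon: no evidence either way
    has_ties = np.unique(pooled).size < pooled.size
    if min(case_values.size, control_values.size) <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        case_values, control_values, alternative="two-sided",
        method=method, use_continuity=True,
    )
    return float(min(res.pvalue, 1.0))


def fisher_presence_test(
    present_case: int, n_case: int, present_control: int, n_control: int
) -> float:
    """Two-sided Fisher exact p-value for a 2x2 presence/absence table."""
    for present, n, name in (
        (present_case, n_case, "case"),
        (present_control, n_control, "control"),
    ):
        if not (0 <= present <= n) or n <= 0:
            raise ValueError(f"invalid {name} counts: {present}/{n}")
    table = [
        [present_case, n_case - present_case],
        [present_control, n_control - present_control],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DiffFeatureRecord:
    """One taxon's test outcome in one mode."""

    taxon: TaxonLineage
    mode: str  # "abundance" | "presence"
    p_raw: float
    q: float
    direction: str  # "case-enriched" | "control-enriched" | "none"
    effect_summary: dict[str, float] = field(default_factory=dict)
    flagged: bool = False  # constant-zero taxon, untestable


def significant_taxa(
    cohort: LabeledCohort,
    mode: str,
    alpha: float = 0.05,
    threshold_percent: float = 0.0,
) -> list[DiffFeatureRecord]:
    """Test every taxon in one mode and FDR-correct across taxa.

    Presence mode binarizes the profile internally at ``threshold_percent``
    (profiles that are already binary are used as-is). A constant-zero taxon
    gets p = 1 and is flagged, never significant.
    """
    if mode not in ("abundance", "presence"):
        raise ValueError(f"mode must be abundance or presence, got {mode!r}")
    profile = cohort.profile
    case = cohort.labels == 1
    control = ~case
    n_case, n_control = int(case.sum()), int(control.sum())

    if mode == "presence":
        values = profile.values if profile.is_binary else binarize(
            profile, threshold_percent
        ).values
    else:
        if profile.is_binary:
            raise ProfileError("abundance mode needs a non-binary profile")
        values = profile.values

    p_raw = np.ones(profile.n_taxa)
    flagged = np.zeros(profile.n_taxa, dtype=bool)
    effects: list[dict[str, float]] = []
    for j in range(profile.n_taxa):
        col = values[:, j]
        if not np.any(col):
            flagged[j] = True
            effects.append({})
            continue
        if mode == "presence":
            a = int((col[case] > 0).sum())
            b = int((col[control] > 0).sum())
            p_raw[j] = fisher_presence_test(a, n_case, b, n_control)
            effects.append(
                {"prevalence_case": a / n_case, "prevalence_control": b / n_control}
            )
        else:
            p_raw[j] = mannwhitney_test(col[case], col[control])
            ranks = stats.rankdata(col)
            effects.append(
                {
                    "mean_rank_case": float(ranks[case].mean()),
                    "mean_rank_control": float(ranks[control].mean()),
                }
            )
    q = bh_fdr(p_raw)

    records = []
    for j, taxon in enumerate(profile.taxa):
        direction = "none"
        if not flagged[j] and q[j] < alpha:
            eff = effects[j]
            if mode == "presence":
                hi_case = eff["prevalence_case"] > eff["prevalence_control"]
            else:
                hi_case = eff["mean_rank_case"] > eff["mean_rank_control"]
            direction = "case-enriched" if hi_case else "control-enriched"
        records.append(
            DiffFeatureRecord(
                taxon=taxon, mode=mode, p_raw=float(p_raw[j]), q=float(q[j]),
                direction=direction, effect_summary=effects[j], flagged=bool(flagged[j]),
            )
        )
    return records


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement between abundance-mode and presence-mode significance calls."""

    n_sig_abundance: int
    n_sig_presence: int
    shared_fraction: float  # significant in both / significant in either
    direction_discrepancy_fraction: float  # direction flips / significant in either
    p_value_correlation: float  # Spearman of -log10 p over the union


def concordance(
    records_abundance: Sequence[DiffFeatureRecord],
    records_presence: Sequence[DiffFeatureRecord],
    alpha: float = 0.05,
) -> ConcordanceReport:
    a_by_taxon = {r.taxon.source_string: r for r in records_abundance}
    p_by_taxon = {r.taxon.source_string: r for r in records_presence}
    if set(a_by_taxon) != set(p_by_taxon):
        raise ProfileError("record lists cover different taxon universes")

    sig_a = {t for t, r in a_by_taxon.items() if r.q < alpha}
    sig_p = {t for t, r in p_by_taxon.items() if r.q < alpha}
    union = sig_a | sig_p
    both = sig_a & sig_p
    shared = len(both) / len(union) if union else float("nan")
    flips = sum(
        1 for t in both if a_by_taxon[t].direction != p_by_taxon[t].direction
    )
    discrepancy = flips / len(union) if union else 0.0
    taxa = sorted(union)
    la = np.array([-np.log10(max(a_by_taxon[t].p_raw, 1e-300)) for t in taxa])
    lp = np.array([-np.log10(max(p_by_taxon[t].p_raw, 1e-300)) for t in taxa])
    if len(union) >= 3 and np.unique(la).size > 1 and np.unique(lp).size > 1:
        rho = float(stats.spearmanr(la, lp).statistic)
    else:
        rho = float("nan")  # too few points or constant p-values
    return ConcordanceReport(
        n_sig_abundance=len(sig_a),
        n_sig_presence=len(sig_p),
        shared_fraction=shared,
        direction_discrepancy_fraction=discrepancy,
        p_value_correlation=rho,
    )


def per_disease_aggregation(
    records_by_disease: Mapping[str, Sequence[set[str]]],
) -> dict[str, float]:
    """Fraction of diseases in which each taxon is significant at least once.

    ``records_by_disease`` maps a disease to the per-dataset sets of
    significant taxon identifiers; a taxon scores a hit for a disease when
    it is significant in at least one of that disease's datasets.
    """
    if not records_by_disease:
        raise ValueError("empty disease map")
    n_diseases = len(records_by_disease)
    hits: dict[str, int] = {}
    for sets in records_by_disease.values():
        seen = set().union(*sets) if sets else set()
        for taxon in seen:
            hits[taxon] = hits.get(taxon, 0) + 1
    return {taxon: count / n_diseases for taxon, count in hits.items()}


def records_to_dataframe(records: Sequence[DiffFeatureRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        summary = ";".join(f"{k}={v:.6g}" for k, v in r.effect_summary.items())
        rows.append(
            {
                "taxon": r.taxon.source_string,
                "mode": r.mode,
                "p_raw": r.p_raw,
                "q": r.q,
                "direction": r.direction,
                "effect_summary": summary,
                "flagged": r.flagged,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["taxon", "mode", "p_raw", "q", "direction", "effect_summary", "flagged"],
    )


def write_records(records: Sequence[DiffFeatureRecord], path: str | Path) -> None:
    records_to_dataframe(records).to_csv(path, sep="\t", index=False)


def read_records(path: str | Path) -> list[DiffFeatureRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        summary = {}
        if row["effect_summary"]:
            for item in str(row["effect_summary"]).split(";"):
                key, val = item.split("=")
                summary[key] = float(val)
        records.append(
            DiffFeatureRecord(
                taxon=TaxonLineage.from_string(row["taxon"]),
                mode=row["mode"],
                p_raw=float(row["p_raw"]),
                q=float(row["q"]),
                direction=row["direction"],
                effect_summary=summary,
                flagged=bool(row["flagged"] in (True, "True", "true", 1, "1")),
            )
        )
    return records
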