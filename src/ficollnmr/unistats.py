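"""Univariate metabolite statistics.

Wilcoxon rank-sum (unpaired) and signed-rank (paired) tests, Benjamini-
Hochberg FDR adjustment across the metabolites of one contrast, and -log2
fold changes of group median intensities.

Conventions
-----------
* Rank-sum: exact null enumeration when the combined sample size is <= 12 and
  there are no ties; otherwise the normal approximation with tie correction.
* Signed-rank: zero differences are dropped (classic Wilcoxon) and their
  count recorded; exact two-sided p by full sign-pattern enumeration for up
  to 14 nonzero differences (valid under tied magnitudes via midranks),
  normal approximation beyond.
* Fold change: ``neg_log2_fold_change(a, b) = -log2(median_a / median_b)``;
  the (A, B) group order is carried in the output metadata, and a
  plain-language ``direction`` column removes any sign ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as ss
from statsmodels.stats.multitest import multipletests

from .chemometrics import SampleAnnotation

EXACT_RANKSUM_MAX_N = 12   # combined n for exact rank-sum (no ties)
EXACT_SIGNRANK_MAX_N = 14  # nonzero pairs for exact sign-pattern enumeration


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when ``len(x) + len(y) <= 12`` and the pooled values
    are tie-free; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_RANKSUM_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(ss.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def _signed_rank_exact(d: np.ndarray) -> float:
    """Two-sided exact p by enumerating all 2^n sign patterns (midranks)."""
    n = d.size
    ranks = ss.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    signs = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1  # all patterns
    w_all = signs @ ranks
    p_low = np.mean(w_all <= w_obs + 1e-9)
    p_high = np.mean(w_all >= w_obs - 1e-9)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


@dataclass
class SignedRankResult:
    p_value: float
    n_pairs: int
    n_zero_dropped: int
    degenerate: bool


def wilcoxon_signed_rank(pre: Sequence[float], post: Sequence[float],
                         full_result: bool = False) -> float | SignedRankResult:
    """Two-sided Wilcoxon signed-rank p-value on within-pair differences.

    Zero differences are dropped and counted. If every difference is zero the
    result is degenerate with ``p = 1``.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1D arrays of equal length")
    d = post - pre
    nonzero = d[d != 0]
    n_zero = d.size - nonzero.size
    if nonzero.size == 0:
        res = SignedRankResult(1.0, d.size, n_zero, degenerate=True)
        return res if full_result else res.p_value
    if nonzero.size < 2:
        raise ValueError("need at least 2 nonzero differences")
    if nonzero.size <= EXACT_SIGNRANK_MAX_N:
        p = _signed_rank_exact(nonzero)
    else:
        p = float(ss.wilcoxon(nonzero, zero_method="wilcox",
                              alternative="two-sided", method="approx",
                              correction=True).pvalue)
    res = SignedRankResult(p, d.size, n_zero, degenerate=False)
    return res if full_result else res.p_value


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def neg_log2_fold_change(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """-log2 of the ratio of group median intensities, ``-log2(med_a/med_b)``.

    Antisymmetric under group swap. A zero or negative median makes the fold
    change undefined and NaN is returned.
    """
    med_a = float(np.median(np.asarray(group_a, dtype=float)))
    med_b = float(np.median(np.asarray(group_b, dtype=float)))
    if med_a <= 0 or med_b <= 0:
        return float("nan")
    return float(-np.log2(med_a / med_b))


def _direction(fc: float, label_a: str, label_b: str) -> str:
    if not np.isfinite(fc) or fc == 0:
        return "unchanged"
    # fc = -log2(med_a/med_b): negative means A has the higher median
    return f"higher-in-{label_a}" if fc < 0 else f"higher-in-{label_b}"


def parse_contrast(contrast) -> tuple[str, tuple[str, ...]]:
    """Normalize a contrast spec.

    Accepts ``"group:CRC,LC"``, ``"paired:timepoint"``,
    ``"anesthetic:etomidate,propofol-2"`` or an equivalent tuple.
    """
    if isinstance(contrast, str):
        kind, _, rest = contrast.partition(":")
        values = tuple(v for v in rest.split(",") if v)
    else:
        kind, values = contrast[0], tuple(contrast[1])
    kind = kind.strip()
    if kind == "paired":
        if values not in ((), ("timepoint",)):
            raise ValueError("paired contrast must be 'paired:timepoint'")
        return "paired", ("pre", "post")
    if kind in ("group", "anesthetic"):
        if len(values) != 2:
            raise ValueError(f"{kind} contrast needs exactly two labels")
        return kind, values
    raise ValueError(f"unknown contrast kind {kind!r}")


def univariate_screen(table: pd.DataFrame,
                      annotations: Sequence[SampleAnnotation],
                      contrast="group:CRC,LC", alpha: float = 0.05,
                      ) -> pd.DataFrame:
    """Screen every metabolite of a table for a group or paired effect.

    Parameters
    ----------
    table
        Samples x metabolites relative concentrations, indexed by sample_id.
    contrast
        ``"group:A,B"`` / ``"anesthetic:A,B"`` (rank-sum on groups A vs B) or
        ``"paired:timepoint"`` (signed-rank on post - pre within subjects).
    alpha
        BH-adjusted significance threshold (one BH family per contrast).

    Returns a DataFrame with columns metabolite, test, p, adjusted_p,
    neg_log2_fc, direction, n_a, n_b, significant; group order metadata is in
    ``result.attrs``.
    """
    kind, (label_a, label_b) = parse_contrast(contrast)
    ann_by_id = {a.sample_id: a for a in annotations}
    missing = [s for s in table.index if s not in ann_by_id]
    if missing:
        raise ValueError(f"samples without annotation: {missing[:5]}")
    if (table.to_numpy(float) < 0).any():
        raise ValueError("metabolite table must be nonnegative")

    rows = []
    if kind == "paired":
        sub_tp: dict[str, dict[str, str]] = {}
        for s in table.index:
            a = ann_by_id[s]
            sub_tp.setdefault(a.subject_id, {})[a.timepoint] = s
        subjects = sorted(sub_tp)
        bad = [s for s in subjects if set(sub_tp[s]) != {"pre", "post"}]
        if bad:
            raise ValueError(f"unpaired subjects in paired contrast: {bad[:5]}")
        pre_ids = [sub_tp[s]["pre"] for s in subjects]
        post_ids = [sub_tp[s]["post"] for s in subjects]
        for met in table.columns:
            pre = table.loc[pre_ids, met].to_numpy(float)
            post = table.loc[post_ids, met].to_numpy(float)
            res = wilcoxon_signed_rank(pre, post, full_result=True)
            fc = neg_log2_fold_change(pre, post)
            rows.append({"metabolite": met, "test": "signed-rank",
                         "p": res.p_value, "neg_log2_fc": fc,
                         "direction": _direction(fc, label_a, label_b),
                         "n_a": len(pre), "n_b": len(post),
                         "n_zero_dropped": res.n_zero_dropped})
    else:
        attr = "group" if kind == "group" else "anesthetic"
        ids_a = [s for s in table.index if getattr(ann_by_id[s], attr) == label_a]
        ids_b = [s for s in table.index if getattr(ann_by_id[s], attr) == label_b]
        if len(ids_a) < 2 or len(ids_b) < 2:
            raise ValueError(f"contrast {label_a!r} vs {label_b!r} needs >= 2 "
                             "samples per side")
        for met in table.columns:
            va = table.loc[ids_a, met].to_numpy(float)
            vb = table.loc[ids_b, met].to_numpy(float)
            fc = neg_log2_fold_change(va, vb)
            rows.append({"metabolite": met, "test": "rank-sum",
                         "p": wilcoxon_rank_sum(va, vb), "neg_log2_fc": fc,
                         "direction": _direction(fc, label_a, label_b),
                         "n_a": len(va), "n_b": len(vb),
                         "n_zero_dropped": 0})
    out = pd.DataFrame(rows)
    out["adjusted_p"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["adjusted_p"] < alpha
    out = out[["metabolite", "test", "p", "adjusted_p", "neg_log2_fc",
               "direction", "n_a", "n_b", "n_zero_dropped", "significant"]]
    out.attrs["group_a"] = label_a
    out.attrs["group_b"] = label_b
    out.attrs["contrast"] = kind
    out.attrs["alpha"] = alpha
    return out


def _retained_segments(window, exclude):
    """Sub-intervals of ``window`` left after removing ``exclude`` ranges."""
    low, high = window
    edges = [low]
    for lo, hi in sorted(exclude):
        edges += [max(lo, low), min(hi, high)]
    edges.append(high)
    return [(a, b) for a, b in zip(edges[::2], edges[1::2]) if b > a]


def metabolite_table(spectra, library, normalize: bool = True,
                     window: tuple[float, float] = (0.20, 10.00),
                     exclude=((3.30, 6.00),)) -> pd.DataFrame:
    """Integrate each metabolite's quantification region in each spectrum.

    ``spectra`` is a sequence of :class:`~ficollnmr.spectra.Spectrum`;
    ``library`` a sequence of :class:`~ficollnmr.simulate.Metabolite` (or any
    object with ``name`` and ``quant_region``). With ``normalize`` each
    sample's areas are divided by that sample's total spectral area over the
    retained (exclusion-complement) window — the same total-area convention
    used for the bucket table, so the values are relative concentrations from
    normalized spectra.
    """
    from .spectra import integrate_signal  # local import avoids cycle at module load
    segments = _retained_segments(window, exclude)
    rows, totals = {}, {}
    for spec in spectra:
        areas = {m.name: max(integrate_signal(spec, m.quant_region), 0.0)
                 for m in library}
        rows[spec.sample_id] = areas
        totals[spec.sample_id] = sum(integrate_signal(spec, seg)
                                     for seg in segments)
    table = pd.DataFrame.from_dict(rows, orient="index")
    if normalize:
        table = table.div(pd.Series(totals), axis=0)
    return table
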