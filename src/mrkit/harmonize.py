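"""Instrument harmonization for two-sample MR.

Builds the per-variant (beta_exposure, se_exposure, beta_outcome,
se_outcome) quadruples every estimator consumes: outcome effects are
re-oriented to the exposure effect allele (handling allele swaps, strand
complements, and palindromic A/T–G/C variants via allele frequency),
missing outcome variants are replaced by LD proxies, and instrument
independence is enforced by greedy LD clumping.

Thresholds follow the strict-inequality convention: a proxy is admitted
when r² is strictly above ``proxy_r2`` (default 0.7) and a correlated
variant is removed when r² is strictly above ``clump_r2`` (default 0.1)
within the clumping window (default 100 kb).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .summary_io import LDTable, SummaryRecord

logger = logging.getLogger("mrkit")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: effect-allele frequency window inside which a palindromic variant's
#: strand cannot be resolved (conventional ambiguity zone, configurable)
PALINDROME_EAF_WINDOW = (0.42, 0.58)

DIRECT = "direct"
PROXY = "proxy"
DROPPED = "dropped"


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome associations for one instrument, with the
    outcome effect aligned to the exposure effect allele."""

    variant_id: str
    beta_exposure: float = float("nan")
    se_exposure: float = float("nan")
    beta_outcome: float = float("nan")
    se_outcome: float = float("nan")
    status: str = DIRECT
    reason: str | None = None
    proxy_id: str | None = None
    proxy_r2: float | None = None

    def __post_init__(self) -> None:
        if self.status != DROPPED:
            if not (self.se_exposure > 0 and self.se_outcome > 0):
                raise ValueError(f"{self.variant_id}: non-dropped pair needs se > 0")


def _dropped(variant_id: str, reason: str) -> HarmonizedPair:
    return HarmonizedPair(variant_id=variant_id, status=DROPPED, reason=reason)


def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


def align_alleles(
    exposure: SummaryRecord,
    outcome: SummaryRecord,
    *,
    palindrome_eaf_window: tuple[float, float] = PALINDROME_EAF_WINDOW,
) -> HarmonizedPair:
    """Align one outcome record to the exposure effect allele.

    Resolution order: direct allele match (possibly swapped, negating the
    outcome beta), then strand complement, then — for palindromic variants,
    where allele labels cannot distinguish strands — orientation by allele
    frequency. A palindromic variant is kept only when both frequencies lie
    outside the ambiguity window; orientation concordance (both minor or
    both major) keeps the outcome beta, discordance negates it.
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValueError("align_alleles requires matching variant ids")
    ea_x, oa_x = exposure.effect_allele, exposure.other_allele
    ea_y, oa_y = outcome.effect_allele, outcome.other_allele

    def keep(beta: float) -> HarmonizedPair:
        return HarmonizedPair(
            variant_id=exposure.variant_id,
            beta_exposure=exposure.beta,
            se_exposure=exposure.se,
            beta_outcome=beta,
            se_outcome=outcome.se,
            status=DIRECT,
        )

    if _is_palindromic(ea_x, oa_x):
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return _dropped(exposure.variant_id, "allele_mismatch")
        lo, hi = palindrome_eaf_window
        if exposure.eaf is None or outcome.eaf is None:
            return _dropped(exposure.variant_id, "palindromic_ambiguous")
        # frequency of the exposure effect allele in the outcome sample,
        # as labelled (labels may refer to either strand — frequency decides)
        eaf_y = outcome.eaf if ea_y == ea_x else 1.0 - outcome.eaf
        if not (exposure.eaf < lo or exposure.eaf > hi) or not (
            eaf_y < lo or eaf_y > hi
        ):
            return _dropped(exposure.variant_id, "palindromic_ambiguous")
        concordant = (exposure.eaf < 0.5) == (eaf_y < 0.5)
        beta_labelled = outcome.beta if ea_y == ea_x else -outcome.beta
        return keep(beta_labelled if concordant else -beta_labelled)

    if {ea_y, oa_y} == {ea_x, oa_x}:
        return keep(outcome.beta if ea_y == ea_x else -outcome.beta)
    comp_ea, comp_oa = COMPLEMENT[ea_y], COMPLEMENT[oa_y]
    if {comp_ea, comp_oa} == {ea_x, oa_x}:
        return keep(outcome.beta if comp_ea == ea_x else -outcome.beta)
    return _dropped(exposure.variant_id, "allele_mismatch")


@dataclass(frozen=True)
class ProxyDecision:
    variant_id: str
    proxy_id: str | None
    r2: float | None
    reason: str | None = None


def substitute_proxies(
    missing: Sequence[str],
    outcome_stats: Iterable[SummaryRecord],
    ld: LDTable,
    r2_min: float = 0.7,
) -> dict[str, ProxyDecision]:
    """Pick an LD proxy among available outcome variants for each missing
    instrument.

    The candidate with the highest r² strictly above ``r2_min`` wins; ties
    break on smaller pair distance, then lexicographic variant id. With no
    admissible candidate the variant is dropped (``no_proxy``).
    """
    available = {r.variant_id for r in outcome_stats}
    decisions: dict[str, ProxyDecision] = {}
    for vid in missing:
        best: tuple[float, int, str] | None = None
        for cand in ld.partners(vid):
            if cand not in available:
                continue
            r2 = ld.r2(vid, cand)
            if r2 is None or not (r2 > r2_min):
                continue
            dist = ld.distance(vid, cand) or 0
            key = (-r2, dist, cand)
            if best is None or key < best:
                best = key
        if best is None:
            decisions[vid] = ProxyDecision(vid, None, None, "no_proxy")
        else:
            decisions[vid] = ProxyDecision(vid, best[2], -best[0])
    return decisions


def ld_clump(
    records: Sequence[SummaryRecord],
    ld: LDTable,
    r2_max: float = 0.1,
    window_bp: int = 100_000,
) -> list[str]:
    """Greedy LD clumping: retain index variants in p-value order.

    Variants are visited by ascending p-value (ties: ascending position,
    then variant id); each retained index variant removes every remaining
    variant on the same chromosome within ``window_bp`` whose r² with it is
    strictly above ``r2_max``. Unknown r² is treated as 0 (logged), so a
    sparse LD table never stalls the clump.
    """
    order = sorted(records, key=lambda r: (r.pvalue, r.pos, r.variant_id))
    retained: list[SummaryRecord] = []
    removed: set[str] = set()
    unknown_pairs = 0
    for rec in order:
        if rec.variant_id in removed:
            continue
        conflict = False
        for kept in retained:
            if kept.chrom != rec.chrom or abs(kept.pos - rec.pos) > window_bp:
                continue
            r2 = ld.r2(kept.variant_id, rec.variant_id)
            if r2 is None:
                unknown_pairs += 1
                continue
            if r2 > r2_max:
                conflict = True
                break
        if conflict:
            removed.add(rec.variant_id)
        else:
            retained.append(rec)
    if unknown_pairs:
        logger.warning(
            "ld_clump: %d in-window pairs had no LD data (treated as r2=0)",
            unknown_pairs,
        )
    return [r.variant_id for r in retained]


def build_instruments(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    ld: LDTable,
    *,
    clump_r2: float = 0.1,
    clump_window_bp: int = 100_000,
    proxy_r2: float = 0.7,
    palindrome_eaf_window: tuple[float, float] = PALINDROME_EAF_WINDOW,
) -> list[HarmonizedPair]:
    """Full harmonization: clump the exposure instruments, align each to
    the outcome (via an LD proxy when the variant is absent from the
    outcome file), and return one :class:`HarmonizedPair` per clumped
    instrument — dropped instruments included, with their reason.

    An LD table carries r² but not the sign of the correlation, so a
    proxy's outcome effect is taken as reported: the proxy's effect allele
    is assumed to tag the instrument's effect allele (positively phased
    LD). The synthetic generator produces positively phased blocks, so the
    assumption holds by construction there.
    """
    exp_by_id = {r.variant_id: r for r in exposure}
    out_by_id = {r.variant_id: r for r in outcome}
    retained = ld_clump(list(exposure), ld, r2_max=clump_r2, window_bp=clump_window_bp)
    missing = [vid for vid in retained if vid not in out_by_id]
    proxies = substitute_proxies(missing, outcome, ld, r2_min=proxy_r2)

    pairs: list[HarmonizedPair] = []
    for vid in retained:
        exp_rec = exp_by_id[vid]
        if vid in out_by_id:
            pairs.append(
                align_alleles(
                    exp_rec, out_by_id[vid],
                    palindrome_eaf_window=palindrome_eaf_window,
                )
            )
            continue
        decision = proxies[vid]
        if decision.proxy_id is None:
            pairs.append(_dropped(vid, "no_proxy"))
            continue
        proxy_out = out_by_id[decision.proxy_id]
        aligned = align_alleles(
            exp_rec,
            SummaryRecord(
                variant_id=vid,
                chrom=proxy_out.chrom,
                pos=proxy_out.pos,
                effect_allele=exp_rec.effect_allele,
                other_allele=exp_rec.other_allele,
                eaf=proxy_out.eaf,
                beta=proxy_out.beta,
                se=proxy_out.se,
                pvalue=proxy_out.pvalue,
                n=proxy_out.n,
            ),
            palindrome_eaf_window=palindrome_eaf_window,
        )
        if aligned.status == DROPPED:
            pairs.append(aligned)
        else:
            pairs.append(
                HarmonizedPair(
                    variant_id=vid,
                    beta_exposure=aligned.beta_exposure,
                    se_exposure=aligned.se_exposure,
                    beta_outcome=aligned.beta_outcome,
                    se_outcome=aligned.se_outcome,
                    status=PROXY,
                    proxy_id=decision.proxy_id,
                    proxy_r2=decision.r2,
                )
            )
    return pairs


def harmonization_report(pairs: Sequence[HarmonizedPair]) -> pd.DataFrame:
    """Tabular report: variant, status, reason, proxy identity and r²."""
    return pd.DataFrame(
        {
            "variant_id": [p.variant_id for p in pairs],
            "status": [p.status for p in pairs],
            "reason": [p.reason or "" for p in pairs],
            "proxy_id": [p.proxy_id or "" for p in pairs],
            "proxy_r2": [p.proxy_r2 if p.proxy_r2 is not None else "" for p in pairs],
        }
    )


def write_harmonization_report(
    pairs: Sequence[HarmonizedPair], path: str | Path
) -> None:
    harmonization_report(pairs).to_csv(path, sep="\t", index=False)


__all__ = [
    "HarmonizedPair",
    "ProxyDecision",
    "align_alleles",
    "substitute_proxies",
    "ld_clump",
    "build_instruments",
    "harmonization_report",
    "write_harmonization_report",
    "DIRECT",
    "PROXY",
    "DROPPED",
    "PALINDROME_EAF_WINDOW",
]
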