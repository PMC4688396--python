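"""DNA-normalized allelic imbalance and per-line expression-mode classification.

For each anchor SNP the allelic odds alt/ref are computed in RNA and DNA with
a Haldane-style pseudocount (0.5 added to all four counts) so that zero
minor-allele RNA reads — the typical monoallelic signature — yield a finite
ratio. The RNA/DNA odds ratio R removes DNA-level imbalance (sampling noise,
residual copy-number skew); the fold imbalance max(R, 1/R) is compared to a
10-fold cutoff to call the anchor monoallelic. A line with anchors that
unanimously call monoallelic (resp. biallelic) takes that mode; anchors are
mutually unphased, so conflicting anchors yield an explicit DISCORDANT call
rather than a vote.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_model import AlleleDepth, ConfigError

MONOALLELIC = "MONOALLELIC"
BIALLELIC = "BIALLELIC"
DISCORDANT = "DISCORDANT"
UNEVALUABLE = "UNEVALUABLE"

REF = "REF"
ALT = "ALT"

#: Supported cutoff comparators: fold >= threshold (default) or strictly >.
COMPARATORS = (">=", ">")


@dataclass(frozen=True)
class ImbalanceResult:
    """Allelic imbalance at one anchor.

    ``fold_imbalance`` = max(R, 1/R) ≥ 1 where R = odds_rna / odds_dna and
    odds(x) = (alt + pc) / (ref + pc). ``major_allele`` is the allele
    expressed in excess (ALT if R > 1, REF otherwise; exact ties take REF
    and set ``tie``).
    """

    snp_id: str
    raw_odds_dna: float
    raw_odds_rna: float
    fold_imbalance: float
    major_allele: str
    call: str
    tie: bool = False


@dataclass(frozen=True)
class ExpressionModeCall:
    line_id: str
    mode: str
    per_snp: tuple[ImbalanceResult, ...]


def imbalance_ratio(
    dna: AlleleDepth,
    rna: AlleleDepth,
    pseudocount: float = 0.5,
    fold_threshold: float = 10.0,
    comparator: str = ">=",
    snp_id: str = "",
) -> ImbalanceResult:
    """Quantify DNA-normalized allelic imbalance at one anchor and call it.

    The call is MONOALLELIC iff ``fold_imbalance`` meets ``fold_threshold``
    under ``comparator`` (">=" by default; ">" matches the stricter reading
    of the cutoff), else BIALLELIC.
    """
    if pseudocount <= 0:
        raise ConfigError(f"pseudocount must be > 0, got {pseudocount}")
    if comparator not in COMPARATORS:
        raise ConfigError(f"comparator must be one of {COMPARATORS}, got {comparator!r}")
    odds_dna = (dna.alt_count + pseudocount) / (dna.ref_count + pseudocount)
    odds_rna = (rna.alt_count + pseudocount) / (rna.ref_count + pseudocount)
    ratio = odds_rna / odds_dna
    fold = max(ratio, 1.0 / ratio)
    tie = ratio == 1.0
    major = ALT if ratio > 1.0 else REF
    if comparator == ">=":
        mono = fold >= fold_threshold
    else:
        mono = fold > fold_threshold
    return ImbalanceResult(
        snp_id=snp_id,
        raw_odds_dna=odds_dna,
        raw_odds_rna=odds_rna,
        fold_imbalance=fold,
        major_allele=major,
        call=MONOALLELIC if mono else BIALLELIC,
        tie=tie,
    )


def classify_line(line_id: str, results: Sequence[ImbalanceResult]) -> ExpressionModeCall:
    """Aggregate per-anchor calls into a line-level expression mode.

    Unanimity rule: all anchors MONOALLELIC → MONOALLELIC; all BIALLELIC →
    BIALLELIC; a mix → DISCORDANT; no anchors → UNEVALUABLE.
    """
    if not results:
        return ExpressionModeCall(line_id, UNEVALUABLE, ())
    calls = {r.call for r in results}
    if calls == {MONOALLELIC}:
        mode = MONOALLELIC
    elif calls == {BIALLELIC}:
        mode = BIALLELIC
    else:
        mode = DISCORDANT
    return ExpressionModeCall(line_id, mode, tuple(results))
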