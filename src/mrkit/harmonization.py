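"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR needs both effects expressed per copy of the *same* allele.
For each instrument we align the outcome record to the exposure's effect
allele, handling label swaps (sign flip), strand flips (reverse complement)
and palindromic variants (A/T or C/G, where strand cannot be resolved from
the allele letters).

Palindromic variants are either dropped outright (``policy="drop"``) or
oriented by matching minor alleles (``policy="infer_by_eaf"``): with allele
labels aligned, both effect-allele frequencies should fall on the same side
of 0.5; if they do not, the reported outcome effect refers to the opposite
physical allele and its sign is flipped.  Frequencies too close to 0.5 (the
ambiguity band) carry no strand information and the variant is removed.
The recorded ``action`` names the *net numeric* transformation applied to
the outcome effect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

from .instrument_selection import InstrumentSet
from .summary_data import GwasTable, SummaryRecord

__all__ = ["HarmonizedPair", "HarmonizationReport", "harmonize", "COMPLEMENT"]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Removal reasons
ABSENT = "absent_in_outcome"
MISMATCH = "allele_mismatch"
AMBIGUOUS = "ambiguous_palindromic"


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one variant on a common effect allele.

    ``gamma_hat``/``se_gamma`` are the exposure (instrument-exposure) effect
    and SE; ``Gamma_hat``/``se_Gamma`` the outcome effect and SE, both per
    copy of the exposure's effect allele.
    """

    variant_id: str
    gamma_hat: float
    se_gamma: float
    Gamma_hat: float
    se_Gamma: float
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    action: str = "none"  # none | sign_flip | strand_flip | strand_flip_and_sign_flip
    palindromic: bool = False

    def __post_init__(self) -> None:
        if self.se_gamma <= 0 or self.se_Gamma <= 0:
            raise ValueError("standard errors must be positive")

    def oriented_positive(self) -> "HarmonizedPair":
        """The same pair expressed so that the exposure effect is >= 0."""
        if self.gamma_hat >= 0:
            return self
        return replace(
            self,
            gamma_hat=-self.gamma_hat,
            Gamma_hat=-self.Gamma_hat,
            eaf_exposure=None if self.eaf_exposure is None else 1 - self.eaf_exposure,
            eaf_outcome=None if self.eaf_outcome is None else 1 - self.eaf_outcome,
        )


@dataclass
class HarmonizationReport:
    kept: list[HarmonizedPair]
    removed: list[tuple[str, str]]  # (variant_id, reason)

    def __len__(self) -> int:
        return len(self.kept)

    @property
    def kept_ids(self) -> list[str]:
        return [p.variant_id for p in self.kept]


def _pair(exp: SummaryRecord, out_beta: float, out: SummaryRecord,
          eaf_out: float | None, action: str, palindromic: bool) -> HarmonizedPair:
    return HarmonizedPair(
        variant_id=exp.variant_id,
        gamma_hat=exp.beta,
        se_gamma=exp.se,
        Gamma_hat=out_beta,
        se_Gamma=out.se,
        eaf_exposure=exp.eaf,
        eaf_outcome=eaf_out,
        action=action,
        palindromic=palindromic,
    )


def _harmonize_one(
    exp: SummaryRecord,
    out: SummaryRecord,
    policy: str,
    band: float,
) -> HarmonizedPair | str:
    """Harmonize one variant; return a pair or a removal reason."""
    ea, oa = exp.effect_allele, exp.other_allele

    if exp.palindromic:
        if {out.effect_allele, out.other_allele} != {ea, oa}:
            return MISMATCH
        if policy == "drop":
            return AMBIGUOUS
        # infer_by_eaf: align labels, then orient by minor-allele matching.
        sign = 1.0 if out.effect_allele == ea else -1.0
        eaf = out.eaf if sign > 0 else (None if out.eaf is None else 1 - out.eaf)
        if exp.eaf is None or eaf is None:
            return AMBIGUOUS
        if abs(exp.eaf - 0.5) <= band or abs(eaf - 0.5) <= band:
            return AMBIGUOUS
        if (exp.eaf < 0.5) != (eaf < 0.5):  # minor alleles disagree -> strand flip
            sign, eaf = -sign, 1 - eaf
        # action records the net numeric effect on the reported outcome beta
        action = "none" if sign > 0 else "sign_flip"
        return _pair(exp, sign * out.beta, out, eaf, action, palindromic=True)

    pairs = {
        (ea, oa): ("none", 1.0, False),
        (oa, ea): ("sign_flip", -1.0, False),
        (COMPLEMENT[ea], COMPLEMENT[oa]): ("strand_flip", 1.0, True),
        (COMPLEMENT[oa], COMPLEMENT[ea]): ("strand_flip_and_sign_flip", -1.0, True),
    }
    key = (out.effect_allele, out.other_allele)
    if key not in pairs:
        return MISMATCH
    action, sign, _strand = pairs[key]
    beta = sign * out.beta
    eaf = None if out.eaf is None else (out.eaf if sign > 0 else 1 - out.eaf)
    return _pair(exp, beta, out, eaf, action, palindromic=False)


def harmonize(
    instruments: InstrumentSet | Iterable[str],
    exposure: GwasTable,
    outcome: GwasTable,
    palindromic_policy: str = "infer_by_eaf",
    eaf_ambiguity_band: float = 0.08,
) -> HarmonizationReport:
    """Align outcome statistics to the exposure's effect allele per instrument.

    Removals (variant absent from the outcome GWAS, irreconcilable allele
    pairs, unresolvable palindromes) are reported, never silent.
    """
    if palindromic_policy not in ("drop", "infer_by_eaf"):
        raise ValueError(f"unknown palindromic policy {palindromic_policy!r}")
    ids = list(instruments.variant_ids) if isinstance(instruments, InstrumentSet) else list(instruments)
    if not ids:
        raise ValueError("instrument set is empty; nothing to harmonize")
    kept: list[HarmonizedPair] = []
    removed: list[tuple[str, str]] = []
    for vid in ids:
        exp = exposure.get(vid)
        if exp is None:
            raise KeyError(f"instrument {vid} missing from the exposure table")
        out = outcome.get(vid)
        if out is None:
            removed.append((vid, ABSENT))
            continue
        result = _harmonize_one(exp, out, palindromic_policy, eaf_ambiguity_band)
        if isinstance(result, str):
            removed.append((vid, result))
        else:
            kept.append(result)
    return HarmonizationReport(kept=kept, removed=removed)
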