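"""Ct-based quantifications: comparative Ct, percent-of-input, getPCR.

All formulas assume exponential amplification with a per-cycle efficiency
``e`` (default 2.0, i.e. perfect doubling; no standard curves are fitted).
One cycle of Ct difference therefore corresponds to an e-fold difference in
template.  Technical replicates are averaged on the Ct scale before any delta
is taken, and their SD is propagated as a spread estimate.

Implemented assays:

* comparative Ct (ddct): relative expression normalized to a reference gene
  and a calibrator sample, rq = e^(-ddCt);
* percent of input for FAIRE/ChIP, correcting the input Ct for the fraction
  of lysate it represents;
* ChIP fold enrichment over an IgG control, as a ratio of percent-inputs;
* getPCR remaining allele fraction after genome editing, a double delta of an
  allele-specific amplicon against a non-allelic reference amplicon in edited
  vs control pools (reconstructed from the assay's amplification logic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError

CT_COLUMNS = ("sample", "amplicon", "role", "ct", "replicate")


def _validate_ct(ct: float) -> float:
    ct = float(ct)
    if not 0 < ct < 45:
        raise ValidationError(f"Ct {ct} outside one qPCR run (0, 45)")
    return ct


def mean_ct(cts: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and SD of technical-replicate Cts."""
    arr = np.asarray([_validate_ct(c) for c in cts], dtype=float)
    if arr.size == 0:
        raise InputError("no Ct replicates")
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


@dataclass
class RelativeExpression:
    sample: str
    target: str
    dct: float
    ddct: float
    rq: float
    dct_sd: float


def ddct(
    ct_table: pd.DataFrame,
    target: str,
    reference: str,
    calibrator_sample: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Comparative-Ct relative expression per sample.

    ``ct_table`` holds CtRecord rows (sample, amplicon, role, ct, replicate).
    Technical replicates are averaged first; then per sample
    dCt = Ct_target - Ct_reference, ddCt = dCt - dCt_calibrator and
    rq = efficiency^(-ddCt).  The calibrator's rq is exactly 1.
    """
    if efficiency <= 1:
        raise ValidationError("amplification efficiency must exceed 1")
    missing = [c for c in ("sample", "amplicon", "ct") if c not in ct_table.columns]
    if missing:
        raise InputError(f"Ct table is missing columns {missing}")
    means: dict[tuple[str, str], tuple[float, float]] = {}
    for (sample, amplicon), grp in ct_table.groupby(["sample", "amplicon"]):
        means[(sample, amplicon)] = mean_ct(grp["ct"])
    samples = sorted(ct_table["sample"].unique())
    for s in samples:
        if (s, reference) not in means:
            raise InputError(f"sample {s!r} lacks a reference ({reference}) Ct")
        if (s, target) not in means:
            raise InputError(f"sample {s!r} lacks a target ({target}) Ct")
    if calibrator_sample not in samples:
        raise InputError(f"calibrator sample {calibrator_sample!r} absent")

    def dct_of(s: str) -> tuple[float, float]:
        (t_mean, t_sd), (r_mean, r_sd) = means[(s, target)], means[(s, reference)]
        return t_mean - r_mean, float(np.hypot(t_sd, r_sd))

    dct_cal, _ = dct_of(calibrator_sample)
    rows = []
    for s in samples:
        dct_s, sd = dct_of(s)
        dd = dct_s - dct_cal
        rows.append(
            RelativeExpression(
                sample=s, target=target, dct=dct_s, ddct=dd,
                rq=float(efficiency ** (-dd)), dct_sd=sd,
            ).__dict__
        )
    return pd.DataFrame(rows)


def percent_input(
    sample_ct: float,
    input_ct: float,
    input_fraction: float,
    efficiency: float = 2.0,
) -> float:
    """Recovered material as a percentage of the (diluted) input control.

    The input Ct is first adjusted down by log_e(1/input_fraction) cycles to
    represent 100% of the chromatin, then
    %input = 100 * efficiency^(adjusted_input_ct - sample_ct).
    """
    if input_fraction <= 0 or input_fraction > 1:
        raise ValidationError("input_fraction must lie in (0, 1]")
    if efficiency <= 1:
        raise ValidationError("amplification efficiency must exceed 1")
    _validate_ct(sample_ct), _validate_ct(input_ct)
    adjusted = input_ct - np.log(1.0 / input_fraction) / np.log(efficiency)
    return float(100.0 * efficiency ** (adjusted - sample_ct))


def chip_fold_over_igg(
    flag_ct: float,
    igg_ct: float,
    input_ct: float,
    input_fraction: float,
    efficiency: float = 2.0,
) -> dict[str, float]:
    """ChIP enrichment of the specific antibody over the IgG mock control.

    Both pulldowns are expressed as percent of input; their ratio simplifies
    to efficiency^(igg_ct - flag_ct).
    """
    pi_flag = percent_input(flag_ct, input_ct, input_fraction, efficiency)
    pi_igg = percent_input(igg_ct, input_ct, input_fraction, efficiency)
    return {
        "percent_input_flag": pi_flag,
        "percent_input_igg": pi_igg,
        "fold": pi_flag / pi_igg,
    }


def getpcr_remaining_fraction(
    allele_ct_edited: float,
    allele_ct_control: float,
    ref_ct_edited: float,
    ref_ct_control: float,
    efficiency: float = 2.0,
) -> float:
    """Fraction of the targeted allele remaining after genome editing.

    Allele-specific qPCR against a non-allelic reference amplicon, edited vs
    unedited pools:
    fraction = e^(-[(Ct_allele,edited - Ct_ref,edited) -
                   (Ct_allele,control - Ct_ref,control)]).
    Editing efficiency is 1 - fraction.
    """
    if efficiency <= 1:
        raise ValidationError("amplification efficiency must exceed 1")
    for ct in (allele_ct_edited, allele_ct_control, ref_ct_edited, ref_ct_control):
        if ct is None:
            raise InputError("all four Ct arms are required")
        _validate_ct(ct)
    dd = (allele_ct_edited - ref_ct_edited) - (allele_ct_control - ref_ct_control)
    return float(efficiency ** (-dd))
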