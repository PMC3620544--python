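"""Relative qRT-PCR quantification by the comparative Ct method."""

from __future__ import annotations

import math
from typing import NamedTuple


class QpcrRecord(NamedTuple):
    gene: str
    reference_gene: str
    ct_target_sample: float
    ct_ref_sample: float
    ct_target_calibrator: float
    ct_ref_calibrator: float


def delta_delta_ct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression 2^-ddCt.

    ddCt = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator,
    assuming ~100% amplification efficiency for both target and the
    reference (e.g. ubiquitin) gene.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if not all(math.isfinite(c) and c > 0 for c in cts):
        raise ValueError(f"Ct values must be positive and finite, got {cts}")
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return 2.0 ** (-ddct)


def relative_expression(record: QpcrRecord) -> float:
    return delta_delta_ct(
        record.ct_target_sample,
        record.ct_ref_sample,
        record.ct_target_calibrator,
        record.ct_ref_calibrator,
    )
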