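"""Core record type shared across the package."""

from __future__ import annotations

from dataclasses import dataclass

PEPTIDE_MAX_LEN = 15


@dataclass(frozen=True)
class BindingRecord:
    """One peptide-allele measurement.

    ``measurement_kind`` is ``"ic50"`` (``value`` a positive affinity in nM,
    lower = stronger binder) or ``"binary"`` (``value`` in {0, 1}).
    """

    peptide: str
    allele: str
    measurement_kind: str
    value: float

    def __post_init__(self) -> None:
        if self.measurement_kind not in ("ic50", "binary"):
            raise ValueError(
                f"measurement_kind must be 'ic50' or 'binary', got {self.measurement_kind!r}"
            )
        if not 1 <= len(self.peptide) <= PEPTIDE_MAX_LEN:
            raise ValueError(
                f"peptide length must be 1..{PEPTIDE_MAX_LEN}, got {len(self.peptide)}"
                f" ({self.peptide!r})"
            )
        if self.measurement_kind == "ic50" and not self.value > 0:
            raise ValueError(f"ic50 must be positive, got {self.value}")
        if self.measurement_kind == "binary" and self.value not in (0, 1, 0.0, 1.0):
            raise ValueError(f"binary label must be 0 or 1, got {self.value}")
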