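"""Filter bookkeeping shared by the community-assembly and I/O layers."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError


@dataclass
class FilterReport:
    """Audit record for one filtering stage.

    Every record dropped from an analysis (low-richness sampling points,
    fossil sites without a maximum-likelihood estimate, ...) is counted here
    with a reason, so headline counts are auditable without rerunning.
    """

    stage: str
    n_in: int = 0
    n_out: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out

    def drop(self, reason: str, n: int = 1) -> None:
        self.reasons[reason] = self.reasons.get(reason, 0) + n

    def validate(self) -> None:
        if self.n_out + sum(self.reasons.values()) != self.n_in:
            raise ValidationError(
                f"filter report '{self.stage}' inconsistent: "
                f"n_in={self.n_in}, n_out={self.n_out}, reasons={self.reasons}"
            )

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_in": self.n_in,
            "n_out": self.n_out,
            "n_removed": self.n_removed,
            "reasons": dict(self.reasons),
        }
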