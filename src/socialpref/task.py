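"""Economics of the norm-compliance punishment task.

A proposer splits a 100-point pie with a responder by transferring one of
{0, 10, 20, 30, 40, 50} points; both players also hold a fixed endowment of
30 points.  The responder may then spend up to 30 points on punishment, each
point removing five points from the proposer (a 1:5 leverage).  Punishment
lets the responder create advantageous inequality (AI, responder ahead),
equality (E) or tolerate disadvantageous inequality (DI, responder behind).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Tuple

__all__ = [
    "TaskConfig",
    "Trial",
    "InequalityClass",
    "UNREACHABLE",
    "compute_payoffs",
    "min_punishment_to_zero",
    "classify_inequality",
]

#: Sentinel returned when no admissible punishment zeroes the proposer.
UNREACHABLE = -1


class InequalityClass(str, Enum):
    """Post-punishment payoff relation from the responder's point of view."""

    AI = "AI"  # responder ahead (advantageous inequality)
    E = "E"  # equal payoffs
    DI = "DI"  # responder behind (disadvantageous inequality)


@dataclass(frozen=True)
class TaskConfig:
    """Fixed economic parameters of the task.

    Defaults reproduce the original design: 30-point endowments, a 100-point
    pie, transfers in steps of 10 up to half the pie, and a 1:5 punishment
    leverage.  ``points_per_chf`` is a cosmetic conversion used only in
    reports.
    """

    responder_endowment: int = 30
    proposer_endowment: int = 30
    pie: int = 100
    transfer_levels: Tuple[int, ...] = (0, 10, 20, 30, 40, 50)
    punishment_leverage: int = 5
    max_punishment: int = 30
    response_window: float = 7.0
    points_per_chf: int = 100

    def __post_init__(self) -> None:
        for name in ("responder_endowment", "proposer_endowment", "pie",
                     "punishment_leverage", "max_punishment"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.punishment_leverage < 1:
            raise ValueError("punishment_leverage must be >= 1")
        if any(t < 0 or t > self.pie for t in self.transfer_levels):
            raise ValueError("transfer_levels must lie within [0, pie]")


@dataclass(frozen=True)
class Trial:
    """One responder decision with its payoff consequences."""

    transfer: int
    punishment: int
    rt: float
    payoff_responder: int
    payoff_proposer: int
    inequality_class: InequalityClass

    @classmethod
    def build(cls, transfer: int, punishment: int, rt: float,
              cfg: TaskConfig | None = None) -> "Trial":
        """Construct a trial, deriving payoffs and the inequality class."""
        cfg = cfg or TaskConfig()
        prop, resp = compute_payoffs(transfer, punishment, cfg)
        return cls(transfer=transfer, punishment=punishment, rt=rt,
                   payoff_responder=resp, payoff_proposer=prop,
                   inequality_class=classify_inequality(resp, prop))


def _check_domain(transfer: int, punishment: int | None, cfg: TaskConfig) -> None:
    if transfer not in cfg.transfer_levels:
        raise ValueError(
            f"transfer={transfer} not in allowed levels {cfg.transfer_levels}")
    if punishment is not None:
        if punishment != int(punishment) or not (0 <= punishment <= cfg.max_punishment):
            raise ValueError(
                f"punishment={punishment} outside integer range [0, {cfg.max_punishment}]")


def compute_payoffs(transfer: int, punishment: int,
                    cfg: TaskConfig | None = None) -> Tuple[int, int]:
    """Post-punishment payoffs ``(proposer, responder)`` in points.

    The responder keeps endowment plus transfer minus the punishment spent;
    the proposer keeps endowment plus the unshared pie minus five points per
    punishment point, floored at zero.
    """
    cfg = cfg or TaskConfig()
    _check_domain(transfer, punishment, cfg)
    punishment = int(punishment)
    resp = cfg.responder_endowment + transfer - punishment
    prop = max(0, cfg.proposer_endowment + (cfg.pie - transfer)
               - cfg.punishment_leverage * punishment)
    return prop, resp


def min_punishment_to_zero(transfer: int, cfg: TaskConfig | None = None) -> int:
    """Smallest punishment that drives the proposer's payoff to zero.

    Returns :data:`UNREACHABLE` if no punishment within the responder's
    endowment suffices.  Found by brute-force scan over the integer grid.
    """
    cfg = cfg or TaskConfig()
    _check_domain(transfer, None, cfg)
    for p in range(cfg.max_punishment + 1):
        prop, _ = compute_payoffs(transfer, p, cfg)
        if prop == 0:
            return p
    return UNREACHABLE


def classify_inequality(payoff_responder: int, payoff_proposer: int) -> InequalityClass:
    """AI if the responder ends ahead, DI if behind, E if payoffs are equal."""
    if payoff_responder < 0 or payoff_proposer < 0:
        raise ValueError("payoffs must be non-negative")
    if payoff_responder > payoff_proposer:
        return InequalityClass.AI
    if payoff_responder < payoff_proposer:
        return InequalityClass.DI
    return InequalityClass.E
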