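"""Payoff arithmetic of the norm-compliance punishment game.

Both players hold 30 points; the proposer splits a further 100 by
transferring 0-50 to the responder, who may then spend up to 30 points on
punishment at 1:5 leverage.
"""

from socialpref import TaskConfig, compute_payoffs, min_punishment_to_zero

cfg = TaskConfig()

prop, resp = compute_payoffs(transfer=20, punishment=0, cfg=cfg)
print(f"accept a transfer of 20          -> proposer {prop}, responder {resp}")

prop, resp = compute_payoffs(transfer=20, punishment=20, cfg=cfg)
print(f"punish with 20 points (removes 100) -> proposer {prop}, responder {resp}")

print("\npunishment needed to zero the proposer, per transfer:")
for t in cfg.transfer_levels:
    print(f"  transfer {t:2d}: {min_punishment_to_zero(t, cfg)} points")

# The zeroing cost falls from 26 to 16 points as transfers become fairer:
# creating advantageous inequality is cheapest after a fair offer.
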