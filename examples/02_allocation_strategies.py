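"""Four ways to split memory resource over priority 0.6 / 0.3 / 0.1 items.

Proportional copies the probe probabilities; Flexible is whatever the data
say; Minimizing Error picks the split that minimizes the probe-weighted
expected error^beta; Maximizing Points picks the split that maximizes
expected wager points.  ME flattens the split relative to Proportional
(hedging against catastrophic low-priority errors); MP does the opposite,
abandoning the low-priority item when resource is scarce.
"""

import numpy as np

from vpalloc import (
    ResourceBudget,
    maximize_points_allocation,
    minimize_error_allocation,
    proportional_allocation,
)

budget = ResourceBudget(Jbar_total=3.0, tau=0.5)

print("strategy                      p_high  p_med  p_low")
p = proportional_allocation()
print(f"proportional                   {p[0]:.3f}  {p[1]:.3f}  {p[2]:.3f}")
for beta in (0.5, 1.0, 2.0):
    p = minimize_error_allocation(budget, beta)
    print(f"minimizing error (beta={beta:3.1f})    {p[0]:.3f}  {p[1]:.3f}  {p[2]:.3f}")
p = maximize_points_allocation(budget)
print(f"maximizing points              {p[0]:.3f}  {p[1]:.3f}  {p[2]:.3f}")

small = ResourceBudget(Jbar_total=1.5, tau=0.5)
p = maximize_points_allocation(small)
print(f"maximizing points, low budget  {p[0]:.3f}  {p[1]:.3f}  {p[2]:.3f}")
print("\nME underallocates to high and overallocates to low priority relative")
print("to the probe probabilities; MP ignores the low-priority item almost")
print("completely when the total resource is small.")
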