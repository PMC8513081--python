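"""Chance-level confidence limits for small-sample classifier evaluation.

With few evaluation trials a random classifier can stray well above the
nominal 1/M accuracy.  The binomial upper confidence bound gives the
accuracy a decoder must exceed to be considered above chance.
"""

from mdeeg import chance_limit

print("trials  classes  nominal   chance limit (alpha=0.05)")
for n, m in [(90, 3), (288, 4), (30, 3), (1000, 3)]:
    print(f"{n:6d}  {m:7d}  {100 / m:6.2f}%   {chance_limit(n, m):6.2f}%")
print("-> 90 three-class trials: a decoder below 43.33% is indistinguishable "
      "from guessing; the bound approaches the nominal rate as n grows.")
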