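"""Fit and optimize the decoction extraction process.

Fits the full quadratic desirability model to the packaged 17-run
Box-Behnken design (three factors: first liquid-solid ratio, first and
second extraction times), reports coefficient significances, and locates
the constrained optimum of the overall desirability.
"""

from pathlib import Path

from herbqc.pipeline import PipelineConfig, run_rsm
from herbqc.rsm import TERM_NAMES

OUT = Path("results")
out = run_rsm(PipelineConfig(outdir=OUT))

model, table, opt = out["model"], out["anova"].set_index("source"), out["optimum"]

def _term(t: str) -> str:
    if t == "b0":
        return ""
    i, j = t[1], t[2] if len(t) == 3 else None
    if j is None:
        return f"*x{i}"
    return f"*x{i}^2" if i == j else f"*x{i}*x{j}"


eq = " ".join(f"{model.coef[t]:+.4f}{_term(t)}" for t in TERM_NAMES)
print(f"fitted OD model (coded units): OD = {eq}")
print(f"R^2 = {model.r_squared:.4f}")
print(f"model p = {table.loc['model', 'p']:.2e}; "
      f"linear-term p: " + ", ".join(
          f"{t}={table.loc[t, 'p']:.4f}" for t in ("b1", "b2", "b3")))
print(f"lack of fit p = {table.loc['lack_of_fit', 'p']:.3f} "
      "(not significant: the quadratic is adequate)")

names = [f.name for f in out["design"].factors]
point = ", ".join(f"{n} = {v:.3f}" for n, v in zip(names, opt.argmax_actual))
print(f"optimum: {point}")
print(f"predicted OD at optimum: {opt.predicted:.3f}")
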