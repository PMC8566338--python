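"""Evaluation metrics on a small hand-built ranking.

Shows the top-k% precision cutoff convention, the jackknife cumulative
curve, and the overlap statistics used to compare two methods' top lists.
"""

from essrank import evaluation as ev

ranking = [f"p{i:02d}" for i in range(20)]
essential = {"p00", "p01", "p03", "p07", "p12"}

topk = ev.topk_precision(ranking, essential, percents=[10, 25, 50])
for p, blk in topk.items():
    print(f"top {p}% -> cutoff ceil({p}/100 * 20) = {blk['cutoff']}, "
          f"{blk['hits']} essentials, precision {blk['precision']:.1f}%")

curve = ev.jackknife_curve(ranking, essential, depth=10)
print("\njackknife curve (cumulative essentials among top r):",
      curve.tolist())

# with the real yeast network size the same convention gives the familiar
# cutoffs 51 (1%) and 1,274 (25%)
print("\ncutoffs at N=5093:", ev.topk_cutoff(1, 5093), ev.topk_cutoff(25, 5093))

method_a = set(ranking[:8])
method_b = set(ranking[4:12])
stats = ev.overlap_diff(method_a, method_b, essential)
print("\noverlap of two top-8 lists:", stats["intersection"],
      "| unique to A:", stats["a_minus_b"],
      f"({stats['essential_pct_a_minus_b']:.0f}% essential)",
      "| unique to B:", stats["b_minus_a"],
      f"({stats['essential_pct_b_minus_a']:.0f}% essential)")
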