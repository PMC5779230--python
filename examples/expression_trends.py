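"""Call increasing/decreasing genes across culture timepoints.

A gene trends when (1) the highest timepoint mean exceeds 3x the lowest,
(2) Welch's t between those timepoints survives FDR < 0.05, and (3) some
timepoint mean exceeds 10 FPKM.
"""

from axoregen import trends as td
from axoregen.synthetic import gen_expression_matrix

matrix, truth = gen_expression_matrix(
    n_genes=500, n_increasing=25, n_decreasing=25, fold=5.0, cv=0.1, seed=9)

calls = td.classify_gene_trends(matrix)
confusion = td.trend_confusion(calls, truth.labels)

counts = {}
for c in calls:
    counts[c.trend] = counts.get(c.trend, 0) + 1
print("calls:", counts)
print(confusion["confusion"].to_string())
print(f"accuracy: {confusion['accuracy']:.3f}")
for cls in ("increasing", "decreasing"):
    print(f"{cls} sensitivity: {confusion['rates'][cls]['sensitivity']:.2f}")
# Rows are planted classes, columns the classifier's calls; off-diagonal
# flat->trending counts come from high-variance genes passing all criteria.
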