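"""Cross-study rank meta-analysis of an androgen-regulated gene cassette.

Simulates five expression studies in which a 25-gene cassette is planted
down-regulated in high-grade tumours while the androgen receptor (AR) is
up-regulated, then asks which genes are consistently extreme in rank across
studies relative to a random-rank null.
"""

from tpsad import (
    ExpressionSimParams,
    geneset_direction_summary,
    meta_analysis,
    simulate_expression_studies,
)
from tpsad.expression import meta_results_frame

params = ExpressionSimParams(n_studies=5, n_genes=1000, samples_per_class=20)
studies = simulate_expression_studies(params, seed=2)
geneset = params.cassette_genes + ["AR"]

results = meta_analysis(studies, geneset, n_perm=5000, seed=0)
frame = meta_results_frame(results).round(4)
print(frame.head(8).to_string(index=False))
print("...")

n_down, n_up, n_total = geneset_direction_summary(
    [r for r in results if r.gene != "AR"], alpha=0.05
)
print(f"\ncassette: {n_down}/{n_total} genes significantly down-regulated "
      f"across studies (alpha=0.05)")
ar = next(r for r in results if r.gene == "AR")
print(f"AR: perm_p_up = {ar.perm_p_up:.4f}, perm_p_down = {ar.perm_p_down:.4f}")
# Every cassette gene ranks near the top of the down-regulated list in all
# five studies (summary_rank_down << 0.5), while AR shows the mirror-image
# pattern: increased receptor expression with a suppressed downstream
# transcriptional program.
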