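"""Enumerate the contexts of the built-in fixtures.

A context is one realized Boolean network: one predictor function chosen
per gene, selected with the product of the per-function probabilities.
"""

from cssbn import build_glioma_scaffold, build_p53_network, enumerate_contexts, top_context_mass

p53 = build_p53_network()
contexts = enumerate_contexts(p53)
print(f"p53-Mdm2 network: {p53.n} genes, {len(contexts)} contexts")
for i, ctx in enumerate(contexts[:4], start=1):
    print(f"  context {i}: predictors {tuple(j + 1 for j in ctx.choice)}, C = {ctx.probability}")
print(f"  ... total selection probability {sum(c.probability for c in contexts):.6f}")

glioma = build_glioma_scaffold()
mass = top_context_mass(glioma, 16)
print(f"\nglioma scaffold: {glioma.n} genes, {glioma.context_count} contexts, "
      f"{glioma.n_states} GAPs")
print(f"  top 16 contexts carry {100 * mass:.2f}% of the selection mass")
print("  -> a 16-context reduction keeps a bit more than half of the context mass,")
print("     which is why intervention studies restrict to the dominant contexts.")
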