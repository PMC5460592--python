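"""Generate a labelled synthetic corpus with exact failure attribution.

Half of the corpus is perturbed, one perturbation per instance, and each
perturbed instance predicts the issues its validation report must show —
which makes the validator itself testable at scale.
"""

from collections import Counter

from dats import GeneratorConfig, Level, generate, validate

config = GeneratorConfig(seed=2, completeness="typical", count=20,
                         invalid_fraction=0.5)
corpus = generate(config)

kinds = Counter(p.kind for item in corpus for p in item.perturbations)
print("perturbations applied:", dict(kinds))

agree = sum(
    1 for item in corpus
    if validate(item.instance).passes(Level.MUST) == item.valid
)
print(f"label/validator agreement: {agree}/{len(corpus)}")

for item in corpus:
    if item.perturbations:
        p = item.perturbations[0]
        print(f"  {p.kind:16s} -> expect {p.expected_code} at {p.path}")
        break
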