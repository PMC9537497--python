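"""Delineate transposable elements, including a nested insertion.

Plants a right-truncated element (its right terminal inverted repeat is
gone) and a complete second element nested inside it — the classic
geometry of one transposon interrupting another — then delineates both
from family descriptors (transposase protein + terminal IR). The child
should carry its 5-bp target-site duplication and point at its parent;
the parent should be flagged right-truncated.
"""

from importlib.resources import files

from plascomp.repeats import delineate_elements, load_descriptors
from plascomp.simulate import SimConfig, generate_query, plant_element

descriptors = load_descriptors(
    files("plascomp").joinpath("data/elements_synthetic.toml")
)
record, truth = generate_query(SimConfig(seed=63, n_genes=6))
record, truth = plant_element(record, truth, descriptors[0], seed=64,
                              truncated="right")
record, truth = plant_element(record, truth, descriptors[1], seed=65,
                              nested_into=0)

calls = delineate_elements(record, descriptors)
print(f"{record.id}: {len(calls)} element calls\n")
for i, c in enumerate(calls):
    parent = f"nested in #{c.parent}" if c.parent is not None else "top-level"
    print(
        f"#{i} {c.family_label:<12} span [{c.span[0]:>6},{c.span[1]:>6})  "
        f"TSD={c.tsd or '-':<6} truncated={c.truncated_side:<5} {parent}"
    )
print(
    "\nSpans come from descriptor-IR matches bracketing each transposase "
    "anchor; the truncated parent's span extends to its child's right "
    "TSD copy, mirroring insertional truncation."
)
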