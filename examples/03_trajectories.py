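"""Phenotypic trajectory analysis over the risk gradient.

Each clone's mean shapes, ordered by rising kairomone concentration,
trace a path through shape space.  Pairs of clones are compared by
path distance (how much shape changes), direction (which landmarks
change) and trajectory shape (how the path bends), each with an RRPP
permutation p-value.
"""

import morphokit as mk

data, _ = mk.simulate(mk.default_spec(), seed=1)
aligned = mk.gpa(data).aligned

result = mk.trajectory_test(
    aligned, group_factor="clone", order_factor="risk",
    n_permutations=999, seed=3, extra_terms=("instar",),
)
print(result.attributes.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

for t in result.trajectories:
    print(f"{t.group}: path distance {mk.path_distance(t):.4f} over {t.L} risk levels")
# A significant p_angle with a non-significant p_magnitude means the
# clones change by similar amounts but in different directions — they
# deploy different parts of the body plan against the same predator.
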