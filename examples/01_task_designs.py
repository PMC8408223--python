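"""Build the three experimental designs and inspect their schedules.

The reaching test (mov) presents 96 targets (3 distances x 8 directions,
each pair 4 times) every 3 s.  The ROT practice block runs 21 sets of 56
reaches with a per-set visuomotor rotation that ramps to 60 deg and always
ends with two unrotated sets; MOT is its unrotated control (20 sets).
"""

from betareach import designs

mov = designs.build_mov_design(seed=1)
rot = designs.build_rot_design(block=1, seed=1)
mot = designs.build_mot_design(seed=1)

print(f"mov : {mov.n_total} presentations, every {mov.inter_target_interval_s} s")
pairs = mov.events_table().groupby(["direction_deg", "distance_cm"]).size()
print(f"      {len(pairs)} unique (direction, distance) targets, each x{pairs.iloc[0]}")

print(f"ROT : {rot.n_sets} sets x {rot.movements_per_set} = {rot.n_total} reaches")
print(f"      rotation by set (deg): {[int(r) for r in rot.rotation_by_set]}")
print(f"      zero-rotation sets for the within-block contrast: {rot.contrast_sets()}")

print(f"MOT : {mot.n_sets} sets x {mot.movements_per_set} = {mot.n_total} reaches,"
      f" all rotations {set(mot.rotation_by_set)}")

# Designs round-trip losslessly through YAML and export a per-trial event table
designs.save_design(rot, "/tmp/rot1.yaml")
back = designs.load_design("/tmp/rot1.yaml")
print("round-trip identical:", back.to_dict() == rot.to_dict())
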