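"""Which cell type becomes the germ-line — and how to bias it.

Under the symmetric model the winner of the reproductive monopoly is a coin
flip across replicate runs.  Giving the type-2 daughter lineage one extra
round of mutation at each development (a slightly larger mutational load)
makes type 1 the germ-line deterministically.

Runs 2 x 6 replicates; takes a few minutes.
"""

import bicell

for preset in ("germline_symmetry", "extra_mutation_type2"):
    rep = bicell.replicate_experiment(preset, n_reps=6, base_seed=11)
    print(f"\n=== {preset} ===")
    print(rep.table[["replicate", "seed", "pz_1", "pz_2", "germline"]]
          .round(3).to_string(index=False))
    print(f"germ-line tally: type1={rep.tally[1]}  type2={rep.tally[2]}  "
          f"unclassified={rep.tally['unclassified']}")

print("""
'germline' is the type with the higher mean reproduction allocation over
the final 10% of cycles (gaps under 0.1 are left unclassified).  The
symmetric preset splits roughly evenly; the extra-mutation variant tallies
overwhelmingly for type 1 (at this desk scale drift still lets an
occasional replicate escape; the bias sharpens with population size).""")
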