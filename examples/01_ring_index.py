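"""Ring Index of hot-spring tetraether lipids, from the packaged tables.

Loads the built-in core-lipid table, recomputes the weighted mean number
of rings per GDGT molecule for a few springs under both weighting
variants, and compares against the value printed alongside each row.
"""

from tetralink import parse_lipid_table, ring_index
from tetralink.pipeline import fixture_path

core = parse_lipid_table(fixture_path("core_lipids.tsv"), "core")

print(f"{'spring':>7} {'printed':>8} {'cren@5':>8} {'cren excluded':>14}")
for profile in core[:6]:
    c5 = ring_index(profile, "cren_weight5")
    pub = ring_index(profile, "as_published")
    print(
        f"{profile.spring_id:>7} {profile.ri_printed:>8.1f} "
        f"{c5:>8.3f} {pub:>14.3f}"
    )

print(
    "\nA ring index near 4 marks an acidic spring dominated by highly "
    "cyclized GDGTs;\nnear 2 an alkaline one.  The printed per-sample "
    "values track the variant that\ncounts crenarchaeol at five rings."
)
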