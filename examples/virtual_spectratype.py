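"""Virtual spectratype reconstruction and three-group classification.

Builds one polyclonal and one oligoclonal repertoire and reconstructs their
per-V-family CDR3 length profiles, scoring each family's Gaussian-ness and
classifying the repertoire as Normal / Almost_normal / Abnormal.
"""

from tcrrecon import simulate_repertoire, spectratype_profile
from tcrrecon.simulate import abnormal_spectratype_params, normal_spectratype_params

for label, params in (
    ("polyclonal", normal_spectratype_params(seed=3)),
    ("oligoclonal", abnormal_spectratype_params(seed=3)),
):
    sample = simulate_repertoire(params, sample_id=label)
    profile = spectratype_profile(sample)
    print(
        f"{label:>12}: classified {profile.classification:<13} "
        f"(median {profile.median_peaks:g} peaks/family, "
        f"{profile.gaussian_fraction:.0%} Gaussian families)"
    )
    f = profile.families[0]
    bins = ", ".join(f"{l}nt:{v / f.total_frequency:.0%}" for l, v in list(f.length_histogram.items())[:6])
    print(f"              {f.v_family} histogram head: {bins}")

print(
    "\nMany 3-nt-spaced peaks under a Gaussian envelope indicate a complex\n"
    "polyclonal repertoire; a few spiked lengths indicate oligoclonal expansion."
)
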