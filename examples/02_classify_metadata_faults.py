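"""Inject each metadata fault class into a synthetic entry and classify it.

The same noisy map is validated against differently corrupted "deposited"
parameters: the true values, nothing at all, a twist-sign flip, swapped
twist/rise, a 5-fold partial symmetry, and unrelated numbers.  Each should
land in its own error class, mirroring the fault taxonomy seen in EMDB
helical depositions.
"""

from helical_validate import (
    HelicalParams,
    default_model,
    flip_sign,
    make_half_maps,
    make_helical_map,
    n_fold,
    swap,
    validate_entry,
)

true = HelicalParams(twist=130.78, rise=9.68, csym=1)
clean = make_helical_map(default_model(), true)
noisy, _ = make_half_maps(clean, noise_sigma=0.15, seed=6)

cases = {
    "true values deposited": true,
    "no values deposited": None,
    "sign flipped": flip_sign(true),
    "twist/rise swapped": swap(true),
    "partial symmetry (n=5)": None,  # needs a smaller rise; built below
    "unrelated values": HelicalParams(94.0, 19.3),
}

for label, deposited in cases.items():
    if label.startswith("partial"):
        small = HelicalParams(57.0, 12.0)
        m_small, _ = make_half_maps(
            make_helical_map(default_model(), small), 0.15, seed=5
        )
        record = validate_entry(m_small, n_fold(small, 5), reported_resolution=5.0)
    else:
        record = validate_entry(noisy, deposited, reported_resolution=5.0)
    extra = f" (multiplier n={record.multiplier})" if record.multiplier else ""
    cc = record.metrics.cc if record.metrics else None
    ccs = (
        f"  cc_dep={cc.cc_deposited:.2f} cc_val={cc.cc_validated:.2f}"
        if cc is not None and deposited is not None or label.startswith("partial")
        else ""
    )
    print(f"{label:24s} -> {record.error_class.value}{extra}{ccs}")

print()
print("cc_dep / cc_val are the symmetrize-and-correlate scores for the")
print("deposited and map-derived parameters; the cascade uses them together")
print("with the resolution-thresholded vector metric to pick the class.")
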