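"""Round-trip a map through MRC and repair a non-standard axis order.

Some deposited maps store voxels with a non-standard axis correspondence
(e.g. Z varying fastest).  The reader records the header's axis order and
``normalize_axes`` transposes the grid back to the standard layout
(X fastest, Z slowest) without moving any voxel physically.
"""

import tempfile
from pathlib import Path

import numpy as np

from helical_validate import (
    DensityMap,
    HelicalParams,
    default_model,
    index_helical_params,
    make_helical_map,
    normalize_axes,
    read_map,
    write_map,
)

density = make_helical_map(default_model(), HelicalParams(57.0, 12.0))

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "helix.mrc"
    write_map(density, path)
    back = read_map(path)
    print(f"round-trip exact: {np.array_equal(back.data, density.data.astype(np.float32))}")
    print(f"voxel size:       {back.voxel_size} A")
    print(f"axes order:       {''.join(back.axes_order)} (fastest to slowest)")

# simulate a deposition whose file was written Z-fastest: same voxels,
# permuted storage plus the matching header declaration
permuted = DensityMap(
    np.ascontiguousarray(density.data.transpose(2, 1, 0)),
    density.voxel_size,
    axes_order=("Z", "Y", "X"),
)
repaired = normalize_axes(permuted)
print(f"repaired order:   {''.join(repaired.axes_order)}")
result = index_helical_params(repaired, with_csym=False)
print(
    f"indexing after repair: twist {result.params.twist:.2f} deg, "
    f"rise {result.params.rise:.2f} A (expected 57, 12)"
)
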