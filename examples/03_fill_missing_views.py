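"""Refill an under-sampled sinogram by three methods and compare errors.

The 180-view analytic sinogram is the truth; 60 measured views are kept
and the missing 120 are estimated.  Smaller max/sum absolute errors mean a
better estimate of the un-measured views.
"""

from radialfill import (fill_views, make_phantom, max_abs_error,
                        sinogram_from_phantom, sum_abs_error,
                        undersample_views)

ph = make_phantom("rotating_features")
full = sinogram_from_phantom(ph, 180, 360.0, 256)
measured = undersample_views(full, keep_every=3)
print(f"measured {measured.n_views} of {full.n_views} views\n")

print(f"{'method':14s} {'max abs err':>12s} {'sum abs err':>12s}")
for method in ("displacement", "sinc", "linear"):
    filled = fill_views(measured, 3, method)
    print(f"{method:14s} {max_abs_error(filled.values, full.values):12.4f} "
          f"{sum_abs_error(filled.values, full.values):12.2f}")
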