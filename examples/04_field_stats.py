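"""Descriptive field computations: transect footprints, multi-stem DBH,
logging tables and duet timing."""

from gibbonascr import (DuetEvent, LoggedTree, TransectLayout,
                        duet_timing_histogram, effective_dbh, logging_summary,
                        transect_footprint_area)

full = TransectLayout()  # 3 observers 40 m apart, 500 m, 20 m margins
print(f"one transect location surveys {transect_footprint_area(full):,.0f} m^2")
print(f"six locations per site: {6 * transect_footprint_area(full):,.0f} m^2")

print(f"\nthree-stem tree with DBHs 10/10/10 cm -> effective DBH "
      f"{effective_dbh([10, 10, 10]):.2f} cm  (preserves basal area)")

trees = [LoggedTree("S1", "Koki", 120.0, 130.0, "2y", True),
         LoggedTree("S1", "Koki", 110.0, None, "<1y", True),   # unmeasurable stump
         LoggedTree("S1", "Thnong", 60.0, 85.0, "5y", False)]
out = logging_summary(trees)
print("\nspecies ranking:")
print(out["species"].to_string())
print("\nKoki stump stats (unmeasured diameters excluded):")
print(out["stumps"].loc["Koki", ["n_total", "n_diameter", "diameter_mean"]])

events = [DuetEvent(f"g{i}", 1, t) for i, t in
          enumerate([-35, -12, -8, -3, 0, 4, 9, 25, 61])]
h = duet_timing_histogram(events)
print(f"\nduet-start histogram (right-closed 10-min bins): "
      f"{{{', '.join(f'{int(k)}: {int(v)}' for k, v in h['counts'].items())}}}")
print(f"modal bin {h['modal_bin']:.0f} holds {100 * h['modal_proportion']:.1f}%"
      f"; {100 * h['window_proportion']:.1f}% fall in the hour from "
      f"30 min before sunrise")
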