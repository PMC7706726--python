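"""Estimate how many firing origins a genome needs: N = G / (2 T v).

On a genome with evenly spaced origins that all fire at S-phase entry,
the simulated completion time is exactly the half-spacing over the fork
speed, and plugging it back into the origin-count formula recovers the
planted number exactly. The same estimate is then computed from a
simulated EdU-incorporation time course, the way T is measured in
practice (time from first incorporation to the plateau).
"""

import oridyn as od
from oridyn import GenomeSpec, OriginEstimateInputs, OriginSpec, SimConfig

spacing, v, n = 120_000, 1.5, 12
genome = GenomeSpec((("chrA", n * spacing),))
origins = [
    OriginSpec("chrA", int((i + 0.5) * spacing), "early", 0.0, 0.0, 1.0) for i in range(n)
]
config = SimConfig(seed=0, n_cells=2, stall_prob=0.0, fork_speed=v)

cell = od.simulate_sphase(genome, origins, config, 100.0).cells[0]
t_complete = cell.completion_time()
value, count = od.estimate_origin_number(OriginEstimateInputs(genome.size_kb, t_complete, v))
print(f"completion time:           {t_complete:.1f} min  (= spacing/(2v) = {spacing/1000/(2*v):.1f})")
print(f"origins from formula:      {value:.2f} -> {count}  (planted: {n})")

timecourse = od.edu_intensity_timecourse(genome, origins, config, list(range(0, 65, 5)))
t_est = od.estimate_replication_time(timecourse)
value2, count2 = od.estimate_origin_number(OriginEstimateInputs(genome.size_kb, t_est, v))
print(f"T from EdU time course:    {t_est:.0f} min (sampled every 5 min)")
print(f"origins from measured T:   {value2:.1f} -> {count2}")
# The time-course estimate is quantized to the 5-min sampling grid, so the
# recovered count is close to, but not exactly, the planted number.
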