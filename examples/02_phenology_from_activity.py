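"""Colony-attendance phenology from immersion and light traces.

Night visits appear as >= 2 h of continuous night-time dryness in the
salt-water immersion trace (the bird is dry in its burrow); incubation day
visits appear as complete daytime darkness in the light trace (the bird
sits in a cave).  The annual-cycle dates recovered from those events are
compared with the simulator's ground truth.
"""

import shearwater as sw

sch = sw.simulate_schedule("Mallorca", 2012, seed=7)
light = sw.simulate_light(sch, twilight_jitter_sd_min=2.0, seed=1)
immersion = sw.simulate_immersion(sch, seed=2)

summary = sw.summarize_bird(
    sch.bird_id, immersion, light, (sch.colony_lon, sch.colony_lat), sch.sex
)

print(f"bird {sch.bird_id} (sex {sch.sex})")
print(f"{'event':<22}{'recovered':<14}truth")
for name in ("last_night_visit", "first_night_visit", "first_day_visit",
             "laying_date", "last_day_visit"):
    print(f"{name:<22}{str(getattr(summary, name)):<14}{sch.truth[name]}")
# last/first night visit bound the non-breeding season (migration
# departure and return); the last day visit proxies the hatching date,
# because daytime cave attendance stops shortly after hatching.
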