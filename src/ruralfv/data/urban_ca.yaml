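# Urban community in California (predecessor setting of the behavior model).
# Education marginals are stored in the only order consistent with nested
# attainment categories (HS-or-higher >= bachelors-or-higher).
name: urban_ca
land_area: 22.97
pop_density: 5969.6
pct_age_18_65: 0.547
pct_female: 0.519
pct_hs_or_higher: 0.612
pct_bachelors_or_higher: 0.279
n_limited_service: 87
n_full_service: 26
n_supermarkets: 2
n_fv_markets: 14
accessibility_radius: 1.0
distance_scale: 1.0
veg_price_index: 0.72
fruit_price_index: 2.71
social_influencability: 0.0
baseline_nearest_fv_distance: 1.0
subsample_factor: 0.05   # full population ~137k agents; proportions are scale-free
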