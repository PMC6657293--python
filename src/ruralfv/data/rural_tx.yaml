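# Rural community in west Texas (2010 census + Food Environment Atlas).
name: rural_tx
land_area: 3.43            # square map-miles
pop_density: 1503.4        # persons per square map-mile
pct_age_18_65: 0.547
pct_female: 0.50
pct_hs_or_higher: 0.664
pct_bachelors_or_higher: 0.08
n_limited_service: 3
n_full_service: 4
n_supermarkets: 2
n_fv_markets: 1
accessibility_radius: 5.0  # real driving miles
distance_scale: 5.0        # 1 map-mile ~ 5 real rural-Texas driving miles
veg_price_index: 0.72
fruit_price_index: 2.71
social_influencability: 0.0
baseline_nearest_fv_distance: 5.0
subsample_factor: 1.0
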