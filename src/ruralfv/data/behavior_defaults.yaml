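behavior:
  w_taste_base: 1.0
  w_price_base: 1.0
  w_access_base: 1.0
  w_health_base: 1.0
  price_weight_boost_low_edu: 1.0
  health_weight_boost_belief: 1.0
  kappa: 1.2
  delta: 3.25
  choice_temperature: 0.35
  servings_pmf_healthy:
  - 0.02
  - 0.08
  - 0.3
  - 0.35
  - 0.15
  - 0.1
  servings_pmf_unhealthy:
  - 0.35
  - 0.35
  - 0.2
  - 0.07
  - 0.02
  - 0.01
  servings_pmf_home:
  - 0.15
  - 0.25
  - 0.3
  - 0.2
  - 0.07
  - 0.03
  p_shop_today: 1.0
  p_belief: 0.5
  servings_tail_tilt: 1.0
  hard_threshold_access: false
  attr_taste:
  - 0.5
  - 0.9
  - 0.8
  - 0.4
  attr_price:
  - 0.6328413284132841
  - 0.5
  - 0.9
  - 0.3
  attr_health:
  - 1.0
  - 0.0
  - 0.2
  - 0.5
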