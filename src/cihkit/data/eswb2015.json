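{
  "indicators": [
    {"name": "urban_gardens_surface", "pillar": "environment", "polarity": "positive"},
    {"name": "green_areas_density", "pillar": "environment", "polarity": "positive"},
    {"name": "historic_green_density", "pillar": "environment", "polarity": "positive"},
    {"name": "pm10_exceedance_days", "pillar": "environment", "polarity": "negative"},
    {"name": "water_network_dispersion", "pillar": "environment", "polarity": "negative"},
    {"name": "noise_limit_exceedances", "pillar": "environment", "polarity": "negative"},
    {"name": "bike_path_density", "pillar": "environment", "polarity": "positive"},
    {"name": "pedestrian_area_availability", "pillar": "environment", "polarity": "positive"},
    {"name": "homicide_rate", "pillar": "social_distress", "polarity": "negative"},
    {"name": "home_theft_rate", "pillar": "social_distress", "polarity": "negative"},
    {"name": "robbery_rate", "pillar": "social_distress", "polarity": "negative"},
    {"name": "road_accident_rate", "pillar": "social_distress", "polarity": "negative"},
    {"name": "public_libraries", "pillar": "culture", "polarity": "positive"},
    {"name": "museums_monuments", "pillar": "culture", "polarity": "positive"},
    {"name": "antiquities_visitors", "pillar": "culture", "polarity": "positive"},
    {"name": "library_users", "pillar": "culture", "polarity": "positive"},
    {"name": "life_expectancy", "pillar": "health", "polarity": "positive"},
    {"name": "infant_mortality", "pillar": "health", "polarity": "negative"},
    {"name": "transport_mortality_15_34", "pillar": "health", "polarity": "negative"},
    {"name": "cancer_mortality_20_64", "pillar": "health", "polarity": "negative"},
    {"name": "dementia_mortality_65_plus", "pillar": "health", "polarity": "negative"},
    {"name": "employment_rate_20_64", "pillar": "work", "polarity": "positive"},
    {"name": "per_capita_gdp", "pillar": "material_wellbeing", "polarity": "positive"}
  ],
  "options": {
    "normalization_mode": "minmax",
    "ampi_direction": "minus",
    "composite_level": "pillars"
  }
}
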