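id,step,category,behavior,valuation_kind,currency,block_capacity,qty_low,qty_base,qty_high,unit_price,role,annual_salary,employer_contribution_rate,social_security_rate,annual_hours,time_low_h,time_base_h,time_high_h,purchase_price,lifetime_low_y,lifetime_base_y,lifetime_high_y,annual_maintenance,area_m2,rate_per_m2_year,storage_gb_low,storage_gb_base,storage_gb_high,price_per_gb_year,storage_years,allocation_weight,note
request_and_logistics,1,personnel,variable,personnel,NOK,,1,1,1,,study_coordinator,642664,0.13,0.25,1695,2.25,3,4.5,,,,,,,,,,,,,1,"request registration, archival tissue retrieval, transport"
sectioning_consumables,2,consumables,variable,unit_price,USD,,1,1,1,21,,,,,,,,,,,,,,,,,,,,,1,"blades, slides, single-use tubes"
pathologist_review,2,personnel,variable,personnel,NOK,,1,1,1,,pathologist,1200000,0.13,0.25,1695,0.375,0.5,0.75,,,,,,,,,,,,,1,tumor evaluation and registration
sectioning_macrodissection,2,personnel,variable,personnel,NOK,,1,1,1,,histotechnician,556743,0.13,0.25,1695,1.05,1.4,2.1,,,,,,,,,,,,,1,
microtome,2,equipment,fixed,equipment,USD,,1,1,1,,,,,,,,,,30000,8,10,12,1200,,,,,,,,1,
histology_space,2,equipment,fixed,space,NOK,,1,1,1,,,,,,,,,,,,,,,9,3388.7611,,,,,,1,
extraction_kit,3,consumables,variable,unit_price,USD,,1,1,1,32.9,,,,,,,,,,,,,,,,,,,,,1,
extraction_handling,3,personnel,variable,personnel,NOK,,1,1,1,,lab_engineer,650000,0.13,0.25,1695,1.39531,1.86041,2.79061,,,,,,,,,,,,,1,
extraction_instrument,3,equipment,fixed,equipment,USD,,1,1,1,,,,,,,,,,110000,8,10,12,5500,,,,,,,,0.7,shared with other assays
extraction_space,3,equipment,fixed,space,NOK,,1,1,1,,,,,,,,,,,,,,,12,2523.0616,,,,,,1,
tso500_library_kit,4,consumables,variable,unit_price,USD,,1,1,1,655,,,,,,,,,,,,,,,,,,,,,1,"per-sample reagent kit, typical rebate"
libprep_qc_reagents,4,consumables,variable,unit_price,USD,,1,1,1,31.1,,,,,,,,,,,,,,,,,,,,,1,
eight_well_strips,4,consumables,step_fixed,unit_price,USD,8,1,1,1,12,,,,,,,,,,,,,,,,,,,,,1,"single-use tube strips, 8 wells"
libprep_hands_on,4,personnel,variable,personnel,NOK,,1,1,1,,lab_engineer,650000,0.13,0.25,1695,1.05913,1.41217,2.11825,,,,,,,,,,,,,1,
libprep_batch_setup,4,personnel,step_fixed,personnel,NOK,64,1,1,1,,lab_engineer,650000,0.13,0.25,1695,5.35512,7.14016,10.71024,,,,,,,,,,,,,1,"per-run protocol blocks, manual workflow"
libprep_thermocyclers,4,equipment,fixed,equipment,USD,,1,1,1,,,,,,,,,,95000,8,10,12,4000,,,,,,,,1,
libprep_qc_station,4,equipment,fixed,equipment,USD,,1,1,1,,,,,,,,,,70000,8,10,12,2500,,,,,,,,1,
libprep_space,4,equipment,fixed,space,NOK,,1,1,1,,,,,,,,,,,,,,,35,2409.9967,,,,,,1,
sequencing_reagents,5,consumables,variable,unit_price,USD,,1,1,1,190.6,,,,,,,,,,,,,,,,,,,,,1,
flow_cell,5,consumables,step_fixed,unit_price,USD,64,1,1,1,986.4,,,,,,,,,,,,,,,,,,,,,1,per run
sequencing_handling,5,personnel,variable,personnel,NOK,,1,1,1,,lab_engineer,650000,0.13,0.25,1695,0.13834,0.18445,0.27668,,,,,,,,,,,,,1,
pooling_and_run_setup,5,personnel,step_fixed,personnel,NOK,64,1,1,1,,lab_engineer,650000,0.13,0.25,1695,3.83784,5.11712,7.67568,,,,,,,,,,,,,1,
sequencer,5,equipment,fixed,equipment,USD,,1,1,1,,,,,,,,,,985000,8,10,12,85000,,,,,,,,0.8,shared across panels
sequencing_space,5,equipment,fixed,space,NOK,,1,1,1,,,,,,,,,,,,,,,20,4870.7629,,,,,,1,
analysis_pipeline_license,5,software_storage,fixed,unit_price,USD,,1,1,1,19422,,,,,,,,,,,,,,,,,,,,,0.8,
pipeline_and_qc,6,personnel,variable,personnel,NOK,,1,1,1,,bioinformatician,800000,0.13,0.25,1695,0.57893,0.77191,1.15786,,,,,,,,,,,,,1,
variant_interpretation,7,personnel,variable,personnel,NOK,,1,1,1,,molecular_biologist,780000,0.13,0.25,1695,3.61681,4.82242,7.23363,,,,,,,,,,,,,1,
variant_db_license,7,software_storage,fixed,unit_price,USD,,1,1,1,1572.48,,,,,,,,,,,,,,,,,,,,,1,
mtb_and_reporting,8,personnel,variable,personnel,NOK,,1,1,1,,mtb_physicians,1200000,0.13,0.25,1695,1.66468,2.21957,3.32936,,,,,,,,,,,,,1,"two-step MTB, report finalization"
mtb_meeting_room,8,equipment,fixed,space,NOK,,1,1,1,,,,,,,,,,,,,,,25,3217.8332,,,,,,0.05,
genomic_data_storage,9,software_storage,variable,storage,USD,,1,1,1,,,,,,,,,,,,,,,,,30,42.8,60,0.02,10,1,"secure server, 10-year retention"
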