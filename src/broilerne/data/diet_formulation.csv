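diet_id,role,ingredient_id,inclusion_pct,energy_yielding,is_test_ingredient
ref,reference,corn,60.82,1,0
ref,reference,soybean_meal,21.42,1,0
ref,reference,corn_gluten_meal,2.60,1,0
ref,reference,peanut_meal,3.00,1,0
ref,reference,soybean_oil,4.50,1,0
ref,reference,ddgs,3.00,1,0
ref,reference,l_lysine_hcl,1.00,1,0
ref,reference,dl_methionine,0.25,1,0
ref,reference,l_threonine,0.14,1,0
ref,reference,monocalcium_phosphate,1.14,0,0
ref,reference,salt,0.25,0,0
ref,reference,sodium_humate,0.20,0,0
ref,reference,choline_chloride,0.11,0,0
ref,reference,sodium_bicarbonate,0.12,0,0
ref,reference,calcium_propionate,0.02,0,0
ref,reference,coarse_stone,0.90,0,0
ref,reference,premix,0.50,0,0
ref,reference,l_tryptophan,0.03,1,0
test_template,test,corn,41.96,1,0
test_template,test,soybean_meal,14.78,1,0
test_template,test,corn_gluten_meal,1.79,1,0
test_template,test,peanut_meal,2.07,1,0
test_template,test,soybean_oil,3.10,1,0
test_template,test,ddgs,2.07,1,0
test_template,test,TEST_INGREDIENT,30.00,1,1
test_template,test,l_lysine_hcl,0.69,1,0
test_template,test,dl_methionine,0.17,1,0
test_template,test,l_threonine,0.10,1,0
test_template,test,monocalcium_phosphate,1.14,0,0
test_template,test,salt,0.25,0,0
test_template,test,sodium_humate,0.20,0,0
test_template,test,choline_chloride,0.11,0,0
test_template,test,sodium_bicarbonate,0.12,0,0
test_template,test,calcium_propionate,0.02,0,0
test_template,test,coarse_stone,0.90,0,0
test_template,test,premix,0.50,0,0
test_template,test,l_tryptophan,0.03,1,0
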