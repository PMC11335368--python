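{"item_id": "gt01", "user_message": "I have had a mild cough for three days. Should I come in?", "ground_truth_response": "Dear patient, a mild cough often improves within a week with rest and fluids. If you develop fever, chest pain, or shortness of breath, or if the cough lasts more than two weeks, please schedule a visit. Best regards.", "ehr_context": {"name": "Alex Doe", "age": "44", "known allergies": "none", "medications": "lisinopril 10 mg daily", "recent clinical note": "Annual wellness visit, no acute issues."}}
{"item_id": "gt02", "user_message": "Is it safe to take ibuprofen with my current medication?", "ground_truth_response": "Dear patient, occasional ibuprofen at the labeled dose is generally acceptable with your current medication, but please take it with food and avoid daily use. If you notice stomach upset or swelling, stop and contact us. Best regards.", "ehr_context": {"name": "Sam Lee", "age": "57", "known allergies": "penicillin", "medications": "metformin 500 mg twice daily", "recent clinical note": "Diabetes follow-up, well controlled."}}
{"item_id": "gt03", "user_message": "My home blood pressure readings have been around 150 over 95.", "ground_truth_response": "Dear patient, thank you for sharing your readings. They are higher than our goal, so please schedule a visit in the next week to review your treatment. If you have chest pain, severe headache, or vision changes, seek urgent care. Best regards.", "ehr_context": {"name": "Jordan Kim", "age": "63", "known allergies": "sulfa drugs", "medications": "amlodipine 5 mg daily", "recent clinical note": "Hypertension follow-up, dose recently adjusted."}}
{"item_id": "gt04", "user_message": "Can you fill out the attached employer health form?", "ground_truth_response": "Dear patient, we have received your form request. Our front desk team will complete it within three business days and it will appear in your portal. Please call the office if you need it sooner. Best regards.", "ehr_context": {"name": "Casey Park", "age": "38", "known allergies": "none", "medications": "none", "recent clinical note": "Routine physical, cleared for work duties."}}
{"item_id": "gt05", "user_message": "My cholesterol panel is in my portal. What do the numbers mean?", "ground_truth_response": "Dear patient, your cholesterol panel shows values within our treatment goals, so no change to your plan is needed. We will repeat the panel in one year. Keep up the healthy diet and activity. Best regards.", "ehr_context": {"name": "Riley Chen", "age": "51", "known allergies": "latex", "medications": "atorvastatin 20 mg nightly", "recent clinical note": "Lipid management, stable."}}
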